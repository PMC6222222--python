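"""Enterprise (SME) side of the market: safety economics and purchase choice.

An enterprise at safety level ``s`` earns safety income ``F(s) = L(s) + I(s)``:
loss reduction ``L(s) = L_scale * exp(l_shape / s) + L0`` and productivity
gain ``I(s) = I_scale * exp(-i_shape / s)``.  Under the self-build strategy
(j1) it operates at its self-built level and pays the safety cost
``C_F(s) = CF_scale * exp(cF_shape / (1 - s)) + C0F``; under the purchase
strategy (j2) it pays the market price instead, adopts the supplier's
quality as its safety level, and bears the accident loss D when an accident
occurs.  Accidents are drawn by roulette: a uniform R in (0, 1) is compared
with the safety level, and an accident occurs iff R exceeds it, so the
accident probability is exactly ``1 - s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ewa import LearnerState
from .params import EconomyParams

__all__ = [
    "J_SELF",
    "J_BUY",
    "safety_reduction",
    "safety_increase",
    "safety_income",
    "factory_safety_cost",
    "self_build_payoff",
    "purchase_payoff_expected",
    "strategy_payoffs",
    "draw_accident",
    "FactoryPopulation",
]

J_SELF = 0  # j1: no purchase, self-build the safety system
J_BUY = 1  # j2: purchase services


def _check_safety_open_unit(s, name: str = "s") -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0.0) or np.any(s >= 1.0):
        raise ValueError(f"{name} must lie strictly inside (0, 1)")
    return s


def safety_reduction(s, econ: EconomyParams) -> np.ndarray:
    """Loss-reduction income L(s); decreasing in s (the exponent l/s falls)."""
    s = _check_safety_open_unit(s)
    return econ.L_scale * np.exp(econ.l_shape / s) + econ.L0


def safety_increase(s, econ: EconomyParams) -> np.ndarray:
    """Productivity income I(s); strictly increasing in s, vanishing at 0."""
    s = _check_safety_open_unit(s)
    return econ.I_scale * np.exp(-econ.i_shape / s)


def safety_income(s, econ: EconomyParams) -> np.ndarray:
    """Total safety income F(s) = L(s) + I(s)."""
    return safety_reduction(s, econ) + safety_increase(s, econ)


def factory_safety_cost(s, econ: EconomyParams) -> np.ndarray:
    """Self-build safety cost C_F(s); strictly increasing, diverging at s=1."""
    s = _check_safety_open_unit(s)
    return econ.CF_scale * np.exp(econ.cF_shape / (1.0 - s)) + econ.C0F


def self_build_payoff(econ: EconomyParams) -> float:
    """Revenue of strategy j1: F(s_self) - C_F(s_self)."""
    s = econ.self_build_safety
    return float(safety_income(s, econ) - factory_safety_cost(s, econ))


def purchase_payoff_expected(quality, econ: EconomyParams) -> np.ndarray:
    """Expected revenue of strategy j2 at a prospective supplier quality.

    ``F(q) - P - (1 - q) * D``: the accident indicator is replaced by its
    expectation ``1 - q`` when the payoff feeds a decision; realized revenue
    uses the drawn indicator instead.
    """
    q = _check_safety_open_unit(quality, "quality")
    return (
        safety_income(q, econ)
        - econ.price_P
        - (1.0 - q) * econ.accident_loss_D
    )


def strategy_payoffs(offered_quality, econ: EconomyParams) -> np.ndarray:
    """Expected payoff vector [j1, j2] given the quality a buyer expects.

    ``offered_quality`` may be a scalar or an array; the result has one
    two-entry row per input quality.
    """
    q = np.atleast_1d(np.asarray(offered_quality, dtype=float))
    u1 = np.full(q.shape, self_build_payoff(econ))
    u2 = purchase_payoff_expected(q, econ)
    return np.stack([u1, u2], axis=-1)


def draw_accident(quality, rng: np.random.Generator) -> np.ndarray:
    """Roulette accident draw: 1 with probability exactly 1 - quality.

    The boundary draw R equal to the safety level counts as safe.
    """
    q = _check_safety_open_unit(quality, "quality")
    r = rng.random(q.shape if q.shape else None)
    return (r > q).astype(np.int8)


@dataclass
class FactoryPopulation:
    """All m enterprises, vectorised.

    Per-tick outcome fields are overwritten by the engine each tick:
    ``purchased`` flags strategy j2, ``supplier`` holds the row index of the
    chosen agency (-1 when self-building), ``safety_level`` the level
    operated at, ``accident`` the drawn indicator (only ever 1 for buyers),
    and ``last_revenue`` the realized revenue.
    """

    learner: LearnerState
    purchased: np.ndarray
    supplier: np.ndarray
    safety_level: np.ndarray
    accident: np.ndarray
    last_revenue: np.ndarray

    @classmethod
    def create(cls, m: int, econ: EconomyParams) -> "FactoryPopulation":
        return cls(
            learner=LearnerState.fresh(m, 2),
            purchased=np.zeros(m, dtype=bool),
            supplier=np.full(m, -1, dtype=np.int64),
            safety_level=np.full(m, econ.self_build_safety),
            accident=np.zeros(m, dtype=np.int8),
            last_revenue=np.zeros(m),
        )

    @property
    def size(self) -> int:
        return self.purchased.shape[0]
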