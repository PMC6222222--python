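"""Service-agency side of the market: cost, profit, quality strategy, exit.

An agency supplying quality ``s`` bears the per-transaction business cost
``C_A(s) = CA_scale * exp(cA_shape / (1 - s)) + C0A`` and earns the
per-transaction profit ``Q(s) = P - C_A(s)``, so higher quality means a
thinner (eventually negative) margin.  Each tick an agency picks one of
three strategies — raise quality by one step, hold, or lower by one step —
via EWA learning over the expected profits of the three candidate
qualities, with government punishment or support folded into the payoffs.

Bookkeeping per agency: gross revenue ("income") of a tick is
``volume * P``; realized profit is ``volume * Q(s)`` minus any fine plus
any subsidy; total assets are the fixed endowment plus cumulative profit
(``KT = GT + sum(pi)``).  An agency exits when its realized profit has been
non-positive for ``exit_loss_streak`` consecutive ticks, when its
cumulative fines exceed the insolvency ratio times its total assets, or
when its total assets are exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ewa import LearnerState
from .government import GRADE_UNRATED
from .params import EconomyParams, InterventionPolicy, RunConfig

__all__ = [
    "K_RAISE",
    "K_HOLD",
    "K_LOWER",
    "agency_cost",
    "single_profit",
    "candidate_qualities",
    "strategy_expected_profits",
    "check_exit",
    "AgencyPopulation",
]

K_RAISE = 0  # k1: improve quality by one step
K_HOLD = 1  # k2: keep quality constant
K_LOWER = 2  # k3: reduce quality by one step


def _check_quality(s, name: str = "s") -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0.0) or np.any(s >= 1.0):
        raise ValueError(f"{name} must lie strictly inside (0, 1)")
    return s


def agency_cost(s, econ: EconomyParams) -> np.ndarray:
    """Per-transaction business cost C_A(s); strictly increasing in s."""
    s = _check_quality(s)
    return econ.CA_scale * np.exp(econ.cA_shape / (1.0 - s)) + econ.C0A


def single_profit(s, econ: EconomyParams) -> np.ndarray:
    """Per-transaction profit Q(s) = P - C_A(s); strictly decreasing in s."""
    return econ.price_P - agency_cost(s, econ)


def candidate_qualities(
    quality: np.ndarray, step: float, lo: float, hi: float
) -> np.ndarray:
    """Qualities reached by raise/hold/lower, clipped to the valid band.

    Returns shape (n, 3) in strategy order (raise, hold, lower).
    """
    q = np.asarray(quality, dtype=float)
    cands = np.stack([q + step, q, q - step], axis=-1)
    return np.clip(cands, lo, hi)


def strategy_expected_profits(
    quality: np.ndarray,
    volume_estimates: np.ndarray,
    policy: InterventionPolicy,
    econ: EconomyParams,
    avg_income: float,
    step: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Expected profit of each strategy, shape (n, 3).

    ``volume_estimates`` holds the anticipated transaction volume per
    strategy (equal across strategies when buyers cannot observe quality;
    grade-class-adjusted under the rating regime).  ``avg_income`` is the
    current industry average gross revenue, entering the anticipated
    subsidy.  Punishment is anticipated on the candidate's own anticipated
    income; under regimes without an intervention value the payoffs reduce
    to volume times per-transaction profit.
    """
    cands = candidate_qualities(quality, step, lo, hi)
    vols = np.asarray(volume_estimates, dtype=float)
    if vols.shape != cands.shape:
        raise ValueError("one volume estimate per strategy is required")
    gross = vols * econ.price_P
    profits = vols * single_profit(cands, econ)
    if policy.regime == "punish":
        breach = cands < policy.punish_standard
        profits = profits - np.where(
            breach, policy.punish_intensity * gross, 0.0
        )
    elif policy.regime == "support":
        eligible = cands > policy.support_standard
        profits = profits + np.where(
            eligible,
            policy.support_intensity
            * (cands - policy.support_standard)
            * avg_income,
            0.0,
        )
    return profits


def check_exit(
    loss_streak: np.ndarray,
    penalty_ledger: np.ndarray,
    total_asset: np.ndarray,
    cfg: RunConfig,
) -> np.ndarray:
    """Alive flags after the exit rules; True means the agency survives.

    Exit on (i) ``exit_loss_streak`` consecutive ticks of non-positive
    profit, (ii) cumulative fines strictly exceeding ``insolvency_ratio``
    times total assets, or (iii) exhausted assets (guard for the ratio's
    domain).  Both threshold comparisons are strict, so an agency exactly
    at a boundary survives.
    """
    dead = loss_streak >= cfg.exit_loss_streak
    dead |= total_asset <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total_asset > 0.0, penalty_ledger / total_asset, np.inf)
    dead |= ratio > cfg.insolvency_ratio
    return ~dead


@dataclass
class AgencyPopulation:
    """All living agencies, vectorised; rows are dropped on exit.

    ``agency_id`` keeps a stable identifier across the run so metrics can
    refer to an agency after reindexing.
    """

    quality: np.ndarray
    learner: LearnerState
    fixed_asset: np.ndarray
    cum_profit: np.ndarray
    penalty_ledger: np.ndarray
    loss_streak: np.ndarray
    last_volume: np.ndarray
    expected_volume: np.ndarray
    last_profit: np.ndarray
    grade: np.ndarray
    agency_id: np.ndarray
    born_tick: np.ndarray

    @classmethod
    def create(
        cls,
        n: int,
        cfg: RunConfig,
        rng: np.random.Generator,
        first_id: int = 0,
        tick: int = 0,
        anticipated_volume: float = 0.0,
    ) -> "AgencyPopulation":
        """Spawn n agencies with fresh learners and uniform initial quality.

        ``anticipated_volume`` seeds the volume expectation of entrants with
        the market's typical per-agency volume, so a newcomer's first
        strategy valuation is not anchored at zero business.
        """
        quality = rng.uniform(cfg.quality_min, cfg.quality_max, size=n)
        return cls(
            quality=quality,
            learner=LearnerState.fresh(n, 3),
            fixed_asset=np.full(n, cfg.initial_fixed_asset),
            cum_profit=np.zeros(n),
            penalty_ledger=np.zeros(n),
            loss_streak=np.zeros(n, dtype=np.int64),
            last_volume=np.zeros(n),
            expected_volume=np.full(n, float(anticipated_volume)),
            last_profit=np.zeros(n),
            grade=np.full(n, GRADE_UNRATED, dtype=np.int8),
            agency_id=np.arange(first_id, first_id + n, dtype=np.int64),
            born_tick=np.full(n, tick, dtype=np.int64),
        )

    @property
    def size(self) -> int:
        return self.quality.shape[0]

    @property
    def total_asset(self) -> np.ndarray:
        """KT = GT + cumulative profit, exactly."""
        return self.fixed_asset + self.cum_profit

    def keep(self, mask: np.ndarray) -> "AgencyPopulation":
        idx = np.nonzero(mask)[0]
        return AgencyPopulation(
            quality=self.quality[idx],
            learner=self.learner.take(idx),
            fixed_asset=self.fixed_asset[idx],
            cum_profit=self.cum_profit[idx],
            penalty_ledger=self.penalty_ledger[idx],
            loss_streak=self.loss_streak[idx],
            last_volume=self.last_volume[idx],
            expected_volume=self.expected_volume[idx],
            last_profit=self.last_profit[idx],
            grade=self.grade[idx],
            agency_id=self.agency_id[idx],
            born_tick=self.born_tick[idx],
        )

    def append(self, other: "AgencyPopulation") -> "AgencyPopulation":
        return AgencyPopulation(
            quality=np.concatenate([self.quality, other.quality]),
            learner=self.learner.append(other.learner),
            fixed_asset=np.concatenate([self.fixed_asset, other.fixed_asset]),
            cum_profit=np.concatenate([self.cum_profit, other.cum_profit]),
            penalty_ledger=np.concatenate(
                [self.penalty_ledger, other.penalty_ledger]
            ),
            loss_streak=np.concatenate([self.loss_streak, other.loss_streak]),
            last_volume=np.concatenate([self.last_volume, other.last_volume]),
            expected_volume=np.concatenate(
                [self.expected_volume, other.expected_volume]
            ),
            last_profit=np.concatenate([self.last_profit, other.last_profit]),
            grade=np.concatenate([self.grade, other.grade]),
            agency_id=np.concatenate([self.agency_id, other.agency_id]),
            born_tick=np.concatenate([self.born_tick, other.born_tick]),
        )
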