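"""Experience-weighted attraction (EWA) learning with logit response.

Both agent populations share this learner: enterprises maintain attractions
over {keep self-building, purchase services}; agencies over {raise, hold,
lower quality}.  Each strategy ``j`` carries an attraction index ``A_j``
updated from payoffs, and an experience weight ``N`` updated as
``N(t) = rho * N(t-1) + 1``.  The chosen strategy's payoff enters the
attraction with weight 1, an unchosen strategy's (foregone, estimated)
payoff with weight ``delta_weight``, and old attractions decay by
``N(t-1) * phi / N(t)``:

    A_j(t) = (N(t-1) * phi * A_j(t-1) + w_j * U_j) / N(t),
    w_j = 1 if j was chosen else delta_weight.

Choice probabilities are the logit (softmax) response
``P_j = exp(lambda * A_j) / sum_k exp(lambda * A_k)``.

The implementation is vectorised: a :class:`LearnerState` holds one row of
attractions per agent so a whole population updates in one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import EWAParams

__all__ = ["LearnerState", "update", "choice_probabilities", "sample_strategy"]


@dataclass
class LearnerState:
    """Attractions and experience weights for a population of learners.

    ``attractions`` has shape (n_agents, n_strategies); ``experience``
    holds the scalar weight N per agent.  Fresh learners start symmetric
    (all attractions zero, N = 1) so initial choice is uniform.
    """

    attractions: np.ndarray
    experience: np.ndarray

    @classmethod
    def fresh(cls, n_agents: int, n_strategies: int) -> "LearnerState":
        return cls(
            attractions=np.zeros((n_agents, n_strategies)),
            experience=np.ones(n_agents),
        )

    @property
    def n_strategies(self) -> int:
        return self.attractions.shape[1]

    def take(self, idx: np.ndarray) -> "LearnerState":
        return LearnerState(self.attractions[idx], self.experience[idx])

    def append(self, other: "LearnerState") -> "LearnerState":
        return LearnerState(
            np.concatenate([self.attractions, other.attractions]),
            np.concatenate([self.experience, other.experience]),
        )


def update(
    state: LearnerState,
    payoffs: np.ndarray,
    chosen: np.ndarray,
    params: EWAParams,
) -> LearnerState:
    """One EWA step for every agent; returns a new state.

    ``payoffs`` holds one entry per strategy and agent (realized payoff for
    the chosen strategy, estimated foregone payoff for the others);
    ``chosen`` is the per-agent index of the adopted strategy.
    """
    payoffs = np.asarray(payoffs, dtype=float)
    if payoffs.shape != state.attractions.shape:
        raise ValueError(
            f"payoff array shape {payoffs.shape} does not match "
            f"attractions shape {state.attractions.shape}"
        )
    chosen = np.asarray(chosen)
    n_agents, n_strategies = payoffs.shape
    if chosen.shape != (n_agents,):
        raise ValueError("one chosen strategy index is required per agent")

    weight = np.full_like(payoffs, params.delta_weight)
    weight[np.arange(n_agents), chosen] = 1.0

    n_old = state.experience
    n_new = params.rho * n_old + 1.0
    attr = (
        n_old[:, None] * params.phi * state.attractions + weight * payoffs
    ) / n_new[:, None]
    return LearnerState(attractions=attr, experience=n_new)


def choice_probabilities(state: LearnerState, lambda_sens: float) -> np.ndarray:
    """Logit response over strategies, one probability row per agent.

    Computed with a max-shift so large attractions cannot overflow.
    """
    if lambda_sens < 0:
        raise ValueError("lambda_sens must be non-negative")
    a = lambda_sens * state.attractions
    a = a - a.max(axis=1, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=1, keepdims=True)


def sample_strategy(probabilities: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one strategy index per agent from its probability row.

    Uses cumulative-sum inversion of a single uniform draw per agent, so a
    fixed generator state yields a reproducible draw sequence.
    """
    p = np.asarray(probabilities, dtype=float)
    squeeze = p.ndim == 1
    if squeeze:
        p = p[None, :]
    cum = np.cumsum(p, axis=1)
    u = rng.random(p.shape[0]) * cum[:, -1]
    idx = (u[:, None] >= cum).sum(axis=1)
    idx = np.minimum(idx, p.shape[1] - 1)
    return idx[0] if squeeze else idx
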