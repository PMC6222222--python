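"""Market engine: the seeded tick loop tying all agents together.

Each tick executes, in fixed order:

1. the government publishes quality grades (rating regime, on its
   inspection schedule);
2. agencies choose a quality strategy (raise / hold / lower) from the
   expected profits of the three candidate qualities;
3. enterprises choose purchase vs. self-build and buyers are matched to
   agencies — uniformly at random when quality is unobservable, uniformly
   within the best published grade under rating;
4. accidents are drawn for buyers from their supplier's quality;
5. settlement: revenues, fines and subsidies are applied;
6. both populations update their learners (realized payoff for the chosen
   strategy, estimated foregone payoff for the others);
7. exit rules are evaluated, then new agencies may enter depending on the
   industry's mean profit;
8. a metrics record is appended.

All randomness flows from one root seed split into named sub-streams
(initialisation, agency choice, factory choice, matching, accidents,
entry), so a (config, seed) pair fully determines the trajectory and
adding draws to one stream cannot perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agency as ag
from . import factory as fa
from .ewa import LearnerState, choice_probabilities, sample_strategy, update
from .government import GRADE_UNRATED, assign_grade
from .params import RunConfig

__all__ = ["MarketState", "MetricsRecord", "new_market", "step", "run", "steady_state_summary"]

_STREAMS = ("init", "agency_choice", "factory_choice", "matching", "accidents", "entry")


@dataclass
class MetricsRecord:
    """Per-tick market summary."""

    tick: int
    mean_quality: float  # unweighted mean over living agencies; NaN when none
    purchase_share: float  # fraction of enterprises that purchased this tick
    n_agencies: int
    accident_count: int
    mean_agency_profit: float
    total_penalties: float
    total_support: float
    deaths: int
    births: int


@dataclass
class MarketState:
    """Full simulation state; advanced in place by :func:`step`."""

    cfg: RunConfig
    tick: int
    factories: fa.FactoryPopulation
    agencies: ag.AgencyPopulation
    rngs: dict[str, np.random.Generator]
    metrics: list[MetricsRecord] = field(default_factory=list)
    # Published inspection results under the rating regime:
    # (tick, agency id, grade) per living agency per inspection.
    grade_log: list[tuple[int, int, int]] = field(default_factory=list)
    next_agency_id: int = 0
    # Industry totals of the previous tick, feeding this tick's expectations.
    last_total_income: float = 0.0
    last_total_buyers: int = 0

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.metrics])

    def grades_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.grade_log, columns=["tick", "agency_id", "grade"]
        )


def new_market(cfg: RunConfig) -> MarketState:
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    rngs = {
        name: np.random.default_rng(seq)
        for name, seq in zip(_STREAMS, root.spawn(len(_STREAMS)))
    }
    factories = fa.FactoryPopulation.create(cfg.n_factories, cfg.economy)
    agencies = ag.AgencyPopulation.create(cfg.n_agencies, cfg, rngs["init"])
    return MarketState(
        cfg=cfg,
        tick=0,
        factories=factories,
        agencies=agencies,
        rngs=rngs,
        next_agency_id=cfg.n_agencies,
    )


def _support_divisor(cfg: RunConfig, n_active: int) -> int:
    if cfg.policy.support_income_divisor == "factories":
        return cfg.n_factories
    return max(n_active, 1)


def _agency_volume_estimates(state: MarketState) -> np.ndarray:
    """Anticipated transaction volume per strategy, shape (n, 3).

    Without published ratings a quality change is invisible to buyers, so
    every candidate inherits the agency's own anticipated volume — a short
    exponential moving average of realized volume, which keeps one lucky or
    unlucky matching draw from dominating the profit forecast.  Under
    rating, a candidate quality maps to a grade and the estimate is the
    mean anticipated volume of that grade's current occupants; an empty
    grade above the market's best is worth the whole buyer pool (a sole
    top-grade agency would capture it), an empty grade below it is worth
    nothing.
    """
    A = state.agencies
    cfg = state.cfg
    base = np.repeat(A.expected_volume[:, None], 3, axis=1)
    if cfg.policy.regime != "rating" or A.size == 0:
        return base
    cands = ag.candidate_qualities(
        A.quality, cfg.quality_step, cfg.quality_min, cfg.quality_max
    )
    cand_grades = assign_grade(cands, cfg.policy)
    rated = A.grade != GRADE_UNRATED
    if not rated.any():
        return base
    best = int(A.grade[rated].max())
    est = np.zeros(3, dtype=float)  # per grade C/B/A
    for g in range(3):
        occupants = rated & (A.grade == g)
        if occupants.any():
            est[g] = float(A.last_volume[occupants].mean())
        elif g > best:
            est[g] = float(state.last_total_buyers)
        else:
            est[g] = 0.0
    return est[cand_grades]


def _factory_belief_quality(state: MarketState) -> float:
    """Quality a prospective buyer expects from the market.

    Quality itself is unobservable, so the belief is the mean quality of
    the agencies a buyer would be matched with: all living agencies
    without ratings, the best published grade class under rating.
    """
    A = state.agencies
    if A.size == 0:
        raise ValueError("belief undefined with no living agency")
    pool = _matching_pool(state)
    return float(A.quality[pool].mean())


def _matching_pool(state: MarketState) -> np.ndarray:
    """Indices of the agencies buyers are matched among."""
    A = state.agencies
    idx = np.arange(A.size)
    if state.cfg.policy.regime == "rating":
        rated = A.grade != GRADE_UNRATED
        if rated.any():
            best = int(A.grade[rated].max())
            return idx[rated & (A.grade == best)]
    return idx


def match(
    n_buyers: int, pool: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Assign each buyer one agency index drawn uniformly from the pool."""
    if pool.size == 0:
        raise ValueError("cannot match buyers with no agency in the pool")
    return pool[rng.integers(0, pool.size, size=n_buyers)]


def step(state: MarketState) -> MarketState:
    """Advance the market by one tick (in place; returns the same object)."""
    cfg = state.cfg
    econ = cfg.economy
    pol = cfg.policy
    F, A = state.factories, state.agencies
    m = F.size

    # (1) Agencies choose and apply a quality strategy.
    if A.size > 0:
        probs_a = choice_probabilities(
            LearnerState(A.learner.attractions, A.learner.experience),
            cfg.ewa.lambda_sens,
        )
        chosen_a = sample_strategy(probs_a, state.rngs["agency_choice"])
        cands = ag.candidate_qualities(
            A.quality, cfg.quality_step, cfg.quality_min, cfg.quality_max
        )
        A.quality = cands[np.arange(A.size), chosen_a]

    # (2) The government inspects current quality and publishes grades.
    if pol.regime == "rating" and A.size > 0 and state.tick % pol.inspection_period == 0:
        A.grade = assign_grade(A.quality, pol)
        state.grade_log.extend(
            zip([state.tick] * A.size, A.agency_id.tolist(), A.grade.tolist())
        )

    # (3) Enterprises choose purchase vs self-build; buyers are matched.
    probs_f = choice_probabilities(F.learner, cfg.ewa.lambda_sens)
    chosen_f = sample_strategy(probs_f, state.rngs["factory_choice"])
    if A.size == 0:
        chosen_f = np.zeros(m, dtype=chosen_f.dtype)  # forced self-build
        belief = np.nan
    else:
        belief = _factory_belief_quality(state)
    buyers = np.nonzero(chosen_f == fa.J_BUY)[0]
    F.purchased[:] = False
    F.supplier[:] = -1
    F.safety_level[:] = econ.self_build_safety
    F.accident[:] = 0
    if buyers.size > 0:
        supplier = match(buyers.size, _matching_pool(state), state.rngs["matching"])
        F.purchased[buyers] = True
        F.supplier[buyers] = A.agency_id[supplier]
        F.safety_level[buyers] = A.quality[supplier]
        # (4) Accidents for buyers only: self-builders bear no accident term.
        F.accident[buyers] = fa.draw_accident(
            F.safety_level[buyers], state.rngs["accidents"]
        )
    else:
        supplier = np.empty(0, dtype=np.int64)

    # (5) Settlement.
    u1 = fa.self_build_payoff(econ)
    F.last_revenue[:] = u1
    if buyers.size > 0:
        F.last_revenue[buyers] = (
            fa.safety_income(F.safety_level[buyers], econ)
            - econ.price_P
            - F.accident[buyers] * econ.accident_loss_D
        )

    total_support = 0.0
    total_penalties = 0.0
    if A.size > 0:
        volume = np.bincount(supplier, minlength=A.size).astype(float)
        income = volume * econ.price_P
        profit = volume * ag.single_profit(A.quality, econ)
        if pol.regime == "punish":
            fine = np.where(
                A.quality < pol.punish_standard, pol.punish_intensity * income, 0.0
            )
            # Only the unpayable part of a fine becomes debt: what the
            # tick's operating profit cannot cover.
            unpayable = np.maximum(fine - np.maximum(profit, 0.0), 0.0)
            profit -= fine
            A.penalty_ledger += unpayable
            total_penalties = float(fine.sum())
        elif pol.regime == "support":
            # The subsidy draws on the industry's observed income of the
            # previous tick (sales plus transfers), the figure the
            # government and the agencies both see when the tick opens.
            avg_income = state.last_total_income / _support_divisor(cfg, A.size)
            subsidy = np.where(
                A.quality > pol.support_standard,
                pol.support_intensity * (A.quality - pol.support_standard) * avg_income,
                0.0,
            )
            profit += subsidy
            total_support = float(subsidy.sum())
        A.cum_profit += profit
        A.last_volume = volume
        # Adaptive volume expectation: EMA with a memory of ~10 ticks.
        A.expected_volume = 0.9 * A.expected_volume + 0.1 * volume
        A.last_profit = profit
        A.loss_streak = np.where(profit > 0.0, 0, A.loss_streak + 1)

    # (6) Learning updates.
    payoffs_f = np.empty((m, 2))
    payoffs_f[:, fa.J_SELF] = u1
    if A.size > 0:
        payoffs_f[:, fa.J_BUY] = fa.purchase_payoff_expected(belief, econ)
    else:
        # No supplier: the purchase option carries no information this tick;
        # its attraction relaxes toward the self-build payoff so a re-entering
        # supply side faces an indifferent, not a permanently deterred, market.
        payoffs_f[:, fa.J_BUY] = u1
    payoffs_f[np.arange(m), chosen_f] = F.last_revenue
    F.learner = update(F.learner, payoffs_f, chosen_f, cfg.ewa)
    if A.size > 0:
        # Foregone payoffs are evaluated at the agency's *current* (post-move)
        # quality with this tick's information, so the attraction of a
        # strategy always prices its consequences from where the agency now
        # stands; the chosen strategy's entry is the realized profit.
        avg_income = float(
            (volume.sum() * econ.price_P) / _support_divisor(cfg, A.size)
        )
        payoffs_a = ag.strategy_expected_profits(
            A.quality,
            _agency_volume_estimates(state),
            pol,
            econ,
            avg_income,
            cfg.quality_step,
            cfg.quality_min,
            cfg.quality_max,
        )
        payoffs_a[np.arange(A.size), chosen_a] = A.last_profit
        A.learner = update(A.learner, payoffs_a, chosen_a, cfg.ewa)

    # (7) Exit, then entry.
    deaths = 0
    if A.size > 0:
        alive = ag.check_exit(A.loss_streak, A.penalty_ledger, A.total_asset, cfg)
        deaths = int((~alive).sum())
        if deaths:
            A = state.agencies = A.keep(alive)
    # Prospective entrants observe the going concerns: the average profit
    # of the agencies still operating after this tick's exits.
    mean_profit = float(A.last_profit.mean()) if A.size > 0 else 0.0
    births = 0
    if cfg.entry_candidate_rate > 0:
        p_entry = float(
            np.clip(
                mean_profit / cfg.entry_profit_scale,
                cfg.entry_prob_min,
                cfg.entry_prob_max,
            )
        )
        candidates = state.rngs["entry"].poisson(cfg.entry_candidate_rate)
        if candidates > 0:
            births = int(state.rngs["entry"].binomial(candidates, p_entry))
        if births > 0:
            typical_volume = (
                state.last_total_buyers / A.size if A.size > 0 else 0.0
            )
            entrants = ag.AgencyPopulation.create(
                births,
                cfg,
                state.rngs["entry"],
                state.next_agency_id,
                state.tick,
                anticipated_volume=typical_volume,
            )
            state.next_agency_id += births
            A = state.agencies = A.append(entrants)

    # (8) Metrics.
    living_prior = A.size  # post exit/entry count
    state.metrics.append(
        MetricsRecord(
            tick=state.tick,
            mean_quality=float(A.quality.mean()) if A.size else float("nan"),
            purchase_share=buyers.size / m,
            n_agencies=living_prior,
            accident_count=int(F.accident.sum()),
            mean_agency_profit=mean_profit,
            total_penalties=total_penalties,
            total_support=total_support,
            deaths=deaths,
            births=births,
        )
    )
    # Industry income as observed from outside: service sales plus any
    # subsidy transfers of the tick.
    state.last_total_income = float(buyers.size * econ.price_P) + total_support
    state.last_total_buyers = int(buyers.size)
    state.tick += 1
    return state


def run(cfg: RunConfig) -> MarketState:
    """Run a full simulation from a validated config."""
    state = new_market(cfg)
    for _ in range(cfg.ticks):
        step(state)
    return state


def steady_state_summary(
    metrics: pd.DataFrame, window: int
) -> dict[str, float]:
    """Trailing-window averages of the two headline observables.

    Returns the means and within-window standard deviations of mean
    service quality and purchase share over the final ``window`` ticks.
    Ticks where no agency lived carry no quality reading and are excluded
    from the quality average.
    """
    if len(metrics) < window:
        raise ValueError(
            f"history of {len(metrics)} ticks is shorter than window {window}"
        )
    tail = metrics.iloc[-window:]
    with np.errstate(invalid="ignore"):
        return {
            "mean_quality": float(np.nanmean(tail["mean_quality"].to_numpy())),
            "mean_quality_sd": float(np.nanstd(tail["mean_quality"].to_numpy())),
            "purchase_share": float(tail["purchase_share"].mean()),
            "purchase_share_sd": float(tail["purchase_share"].std(ddof=0)),
        }
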