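"""Government intervention: punishment, policy support, quality rating.

Three mutually exclusive regimes:

* **punish** — an agency whose service quality is lower than the standard
  S_p is fined ``beta * income`` out of its tick revenue, where ``income``
  is the agency's gross service revenue of the tick.  Quality exactly at
  the standard is not punished.
* **support** — an agency whose quality exceeds the standard S_r receives
  the subsidy ``alpha * (s - S_r) * (industry income / divisor)``; the
  divisor is by default the active agency count (industry average revenue).
  Quality exactly at the standard earns nothing.
* **rating** — the government inspects every living agency and publishes a
  grade: C on [0, 0.4), B on [0.4, 0.7), A on [0.7, 1].  The printed
  interval endpoints are resolved half-open upward (the closed intervals
  would double-assign their boundaries).  Buyers observe grades only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import InterventionPolicy

__all__ = [
    "GRADE_C",
    "GRADE_B",
    "GRADE_A",
    "GRADE_UNRATED",
    "GRADE_NAMES",
    "GradeAssignment",
    "punishment_value",
    "support_value",
    "assign_grade",
    "inspect_and_publish",
]

# Numeric grade codes, ordered so that larger is better.
GRADE_UNRATED = -1
GRADE_C = 0
GRADE_B = 1
GRADE_A = 2
GRADE_NAMES = {GRADE_UNRATED: "unrated", GRADE_C: "C", GRADE_B: "B", GRADE_A: "A"}


@dataclass(frozen=True)
class GradeAssignment:
    """One published inspection result."""

    agency_id: int
    grade: int
    inspected_quality: float
    tick: int


def punishment_value(income, quality, policy: InterventionPolicy) -> np.ndarray:
    """Fine levied on a below-standard agency; zero outside the punish regime.

    The breach is strict: quality exactly at the standard is compliant.
    """
    income = np.asarray(income, dtype=float)
    quality = np.asarray(quality, dtype=float)
    if policy.regime != "punish":
        return np.zeros(np.broadcast(income, quality).shape)
    breach = quality < policy.punish_standard
    return np.where(breach, policy.punish_intensity * income, 0.0)


def support_value(
    quality, industry_income: float, n_active: int, policy: InterventionPolicy
) -> np.ndarray:
    """Subsidy paid to an above-standard agency; zero outside the support regime.

    ``industry_income`` is the total gross revenue of all active agencies
    this tick; the average is taken over ``n_active`` (or the factory count,
    if so configured — the alternative reading of the formula's divisor,
    in which case the caller passes that count).
    """
    quality = np.asarray(quality, dtype=float)
    if policy.regime != "support":
        return np.zeros(quality.shape)
    if n_active < 1:
        raise ValueError("support requires at least one active agency")
    avg_income = industry_income / n_active
    eligible = quality > policy.support_standard
    return np.where(
        eligible,
        policy.support_intensity * (quality - policy.support_standard) * avg_income,
        0.0,
    )


def assign_grade(quality, policy: InterventionPolicy) -> np.ndarray:
    """Map quality to grade C/B/A on the half-open partition of (0, 1)."""
    q = np.asarray(quality, dtype=float)
    if np.any(q <= 0.0) or np.any(q >= 1.0):
        raise ValueError("quality must lie strictly inside (0, 1)")
    lo, hi = policy.rating_bounds
    grades = np.full(q.shape, GRADE_C, dtype=np.int8)
    grades[q >= lo] = GRADE_B
    grades[q >= hi] = GRADE_A
    return grades


def inspect_and_publish(
    qualities: np.ndarray,
    alive: np.ndarray,
    policy: InterventionPolicy,
    tick: int,
) -> list[GradeAssignment]:
    """Grade every living agency from its current true quality.

    Inspection is truthful (no measurement noise).  Dead agencies are not
    published.  Returns the assignments in agency order.
    """
    if policy.regime != "rating":
        raise ValueError("inspection requires the rating regime")
    out: list[GradeAssignment] = []
    grades = assign_grade(np.clip(qualities, 1e-9, 1 - 1e-9), policy)
    for i in np.nonzero(alive)[0]:
        out.append(
            GradeAssignment(
                agency_id=int(i),
                grade=int(grades[i]),
                inspected_quality=float(qualities[i]),
                tick=tick,
            )
        )
    return out
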