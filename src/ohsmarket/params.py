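"""Model constants and run configuration.

Every economic constant of the market model lives here: the safety
income/cost curves of the enterprises (SMEs), the cost curve and price of
the service agencies, the experience-weighted-attraction (EWA) learning
parameters shared by both populations, the government-intervention policy,
and the bookkeeping constants that govern agency exit and entry.

The shipped :func:`default_calibration` is the single frozen parameter set
under which the no-intervention baseline settles at the documented market
state (mean service quality around 0.2, roughly one SME in ten buying
services); all intervention scenarios reuse it unchanged.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

SCHEMA_VERSION = 1

__all__ = [
    "EconomyParams",
    "EWAParams",
    "InterventionPolicy",
    "RunConfig",
    "ConfigError",
    "default_calibration",
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
]


class ConfigError(ValueError):
    """Raised when a configuration file or field fails validation."""


def _require(cond: bool, field_name: str, rule: str) -> None:
    if not cond:
        raise ConfigError(f"invalid value for '{field_name}': {rule}")


@dataclass(frozen=True)
class EconomyParams:
    """Currency-scale constants of the safety economy.

    An enterprise operating at safety level ``s`` earns safety income
    ``F(s) = L(s) + I(s)`` with loss reduction ``L(s) = L_scale*exp(l_shape/s)
    + L0`` and productivity gain ``I(s) = I_scale*exp(-i_shape/s)``, and pays
    safety cost ``C_F(s) = CF_scale*exp(cF_shape/(1-s)) + C0F`` when building
    the safety system itself.  An agency supplying quality ``s`` bears the
    per-transaction business cost ``C_A(s) = CA_scale*exp(cA_shape/(1-s)) +
    C0A`` and charges the uniform market price ``price_P``; ``accident_loss_D``
    is the loss an enterprise suffers when an accident occurs.
    """

    L_scale: float = 1.0
    l_shape: float = 0.01
    L0: float = 20.0
    I_scale: float = 1.2
    i_shape: float = 0.3
    CF_scale: float = 1.0
    cF_shape: float = 1.0
    C0F: float = 5.6
    CA_scale: float = 8.22
    cA_shape: float = 0.043
    C0A: float = 0.01
    price_P: float = 10.2
    accident_loss_D: float = 1.55
    self_build_safety: float = 0.4

    def validate(self) -> None:
        for name in (
            "L_scale",
            "l_shape",
            "L0",
            "I_scale",
            "i_shape",
            "CF_scale",
            "cF_shape",
            "C0F",
            "CA_scale",
            "cA_shape",
            "C0A",
        ):
            _require(getattr(self, name) > 0, name, "must be strictly positive")
        _require(self.price_P > 0, "price_P", "must be strictly positive")
        _require(self.accident_loss_D >= 0, "accident_loss_D", "must be non-negative")
        _require(
            0.0 < self.self_build_safety < 1.0,
            "self_build_safety",
            "must lie strictly inside (0, 1); the cost curves diverge at 1",
        )


@dataclass(frozen=True)
class EWAParams:
    """Experience-weighted attraction learning constants.

    ``rho`` discounts the experience weight, ``phi`` discounts past
    attractions, ``delta_weight`` weights foregone payoffs of unchosen
    strategies, and ``lambda_sens`` is the logit sensitivity mapping
    attractions to choice probabilities.  One set is shared by the
    two-strategy enterprise learners and three-strategy agency learners.
    """

    rho: float = 0.8
    phi: float = 0.8
    delta_weight: float = 1.0
    lambda_sens: float = 2.5

    def validate(self) -> None:
        _require(0.0 <= self.rho <= 1.0, "rho", "must lie in [0, 1]")
        _require(0.0 <= self.phi <= 1.0, "phi", "must lie in [0, 1]")
        _require(
            0.0 <= self.delta_weight <= 1.0, "delta_weight", "must lie in [0, 1]"
        )
        _require(
            self.lambda_sens >= 0.0 and math.isfinite(self.lambda_sens),
            "lambda_sens",
            "must be finite and non-negative",
        )


REGIMES = ("none", "punish", "support", "rating")


@dataclass(frozen=True)
class InterventionPolicy:
    """Government regime selector with its standard and intensity.

    Exactly one regime is active per run.  Under ``punish`` an agency whose
    quality falls below ``punish_standard`` is fined
    ``punish_intensity * (its gross revenue)``.  Under ``support`` an agency
    whose quality exceeds ``support_standard`` receives
    ``support_intensity * (quality - support_standard) * (industry average
    revenue)``.  Under ``rating`` the government inspects every agency and
    publishes grades C/B/A on the quality partition given by
    ``rating_bounds``; buyers then shop among the best published grade.
    """

    regime: str = "none"
    punish_standard: float = 0.6
    punish_intensity: float = 0.8
    support_standard: float = 0.3
    support_intensity: float = 1.5
    rating_bounds: tuple[float, float] = (0.4, 0.7)
    inspection_period: int = 1
    # Divisor of the industry income average in the subsidy formula:
    # "agencies" (active agency count, the default reading) or "factories".
    support_income_divisor: str = "agencies"

    def validate(self) -> None:
        _require(self.regime in REGIMES, "regime", f"must be one of {REGIMES}")
        _require(
            0.0 < self.punish_standard < 1.0, "punish_standard", "must lie in (0, 1)"
        )
        _require(
            self.punish_intensity >= 0.0, "punish_intensity", "must be non-negative"
        )
        _require(
            0.0 < self.support_standard < 1.0, "support_standard", "must lie in (0, 1)"
        )
        _require(
            self.support_intensity >= 0.0, "support_intensity", "must be non-negative"
        )
        lo, hi = self.rating_bounds
        _require(
            0.0 < lo < hi < 1.0,
            "rating_bounds",
            "must be strictly increasing inside (0, 1)",
        )
        _require(
            self.inspection_period >= 1, "inspection_period", "must be at least 1"
        )
        _require(
            self.support_income_divisor in ("agencies", "factories"),
            "support_income_divisor",
            "must be 'agencies' or 'factories'",
        )


@dataclass(frozen=True)
class RunConfig:
    """Complete, validated configuration of one simulation run."""

    n_factories: int = 1000
    n_agencies: int = 20
    ticks: int = 2000
    steady_window: int = 500
    seed: int = 0
    # Agency exit: consecutive non-positive-profit ticks tolerated, and the
    # insolvency ratio (cumulative penalties / total assets) above which an
    # agency goes bankrupt.
    exit_loss_streak: int = 3
    insolvency_ratio: float = 0.5
    # Agency entry: mean number of candidate entrants per tick; each enters
    # with probability clamp(mean industry profit / entry_profit_scale,
    # entry_prob_min, entry_prob_max).
    entry_candidate_rate: float = 0.5
    entry_profit_scale: float = 8.0
    entry_prob_min: float = 0.05
    entry_prob_max: float = 0.9
    # Agency quality dynamics: step of the raise/lower strategies and the
    # admissible quality band (the cost curves diverge at quality 1).
    quality_step: float = 0.05
    quality_min: float = 0.05
    quality_max: float = 0.9
    # Initial endowments.
    initial_fixed_asset: float = 900.0
    economy: EconomyParams = field(default_factory=EconomyParams)
    ewa: EWAParams = field(default_factory=EWAParams)
    policy: InterventionPolicy = field(default_factory=InterventionPolicy)

    def validate(self) -> None:
        _require(self.n_factories >= 1, "n_factories", "must be positive")
        _require(self.n_agencies >= 1, "n_agencies", "must be positive")
        _require(self.ticks >= 0, "ticks", "must be non-negative")
        _require(
            1 <= self.steady_window and self.steady_window <= max(self.ticks, 1),
            "steady_window",
            "must be positive and no longer than the run",
        )
        _require(self.exit_loss_streak >= 1, "exit_loss_streak", "must be positive")
        _require(self.insolvency_ratio > 0, "insolvency_ratio", "must be positive")
        _require(
            self.entry_candidate_rate >= 0,
            "entry_candidate_rate",
            "must be non-negative",
        )
        _require(
            self.entry_profit_scale > 0, "entry_profit_scale", "must be positive"
        )
        _require(
            0.0 <= self.entry_prob_min <= self.entry_prob_max <= 1.0,
            "entry_prob_min",
            "need 0 <= entry_prob_min <= entry_prob_max <= 1",
        )
        _require(
            0.0 < self.quality_step < 0.5, "quality_step", "must lie in (0, 0.5)"
        )
        _require(
            0.0 < self.quality_min < self.quality_max < 1.0,
            "quality_min",
            "need 0 < quality_min < quality_max < 1",
        )
        _require(
            self.initial_fixed_asset > 0, "initial_fixed_asset", "must be positive"
        )
        self.economy.validate()
        self.ewa.validate()
        self.policy.validate()


def default_calibration(**overrides: Any) -> RunConfig:
    """Return the frozen default parameter set, optionally overridden.

    Keyword overrides may address top-level ``RunConfig`` fields directly or
    the nested blocks via ``economy=``, ``ewa=``, ``policy=`` mappings or
    instances.
    """
    cfg = RunConfig()
    if overrides:
        cfg = replace_config(cfg, **overrides)
    cfg.validate()
    return cfg


def replace_config(cfg: RunConfig, **overrides: Any) -> RunConfig:
    """Functional update of a config, accepting nested dict overrides."""
    nested = {"economy": EconomyParams, "ewa": EWAParams, "policy": InterventionPolicy}
    fields: dict[str, Any] = {}
    for key, value in overrides.items():
        if key in nested and isinstance(value, dict):
            fields[key] = dataclasses.replace(getattr(cfg, key), **value)
        else:
            fields[key] = value
    try:
        out = dataclasses.replace(cfg, **fields)
    except TypeError as exc:  # unknown field name
        raise ConfigError(str(exc)) from exc
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Serialization


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    out = dataclasses.asdict(cfg)
    out["policy"]["rating_bounds"] = list(cfg.policy.rating_bounds)
    out["schema_version"] = SCHEMA_VERSION
    return out


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config document must be a mapping")
    data = dict(data)
    version = data.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"invalid value for 'schema_version': expected {SCHEMA_VERSION}, got {version}"
        )
    nested: dict[str, Any] = {}
    for key, cls in (
        ("economy", EconomyParams),
        ("ewa", EWAParams),
        ("policy", InterventionPolicy),
    ):
        block = data.pop(key, None)
        if block is None:
            continue
        if not isinstance(block, dict):
            raise ConfigError(f"invalid value for '{key}': must be a mapping")
        if key == "policy" and "rating_bounds" in block:
            block = dict(block)
            block["rating_bounds"] = tuple(block["rating_bounds"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(block) - known
        if unknown:
            raise ConfigError(f"unknown field '{key}.{sorted(unknown)[0]}'")
        nested[key] = cls(**block)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown field '{sorted(unknown)[0]}'")
    cfg = dataclasses.replace(RunConfig(**data), **nested)
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration from a YAML (or JSON) file."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if data is None:
        data = {}
    return config_from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config as YAML; ``load_config`` restores it exactly."""
    cfg.validate()
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))
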