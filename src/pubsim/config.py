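"""Configuration surface: dataclasses for every tunable block plus YAML/JSON I/O.

A full simulation is described by a :class:`SimulationConfig`, which nests the
journal/population calibration, the review-policy variant, the stage timings
and the assessment-error model.  Everything is a plain dataclass so configs can
be built in code, loaded from YAML, round-tripped and hashed for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import yaml

VARIANTS = ("conventional", "rro", "cascade", "portable", "crowdsourcing", "immediate")
AGGREGATIONS = ("weighted_mean", "average_all", "random_pick")
REPUTATION_LAWS = ("lognormal_rescaled", "uniform")


@dataclass
class ErrorModelParams:
    """Parameters of the editor/reviewer assessment-error model.

    ``reviewing_error_table`` is the categorical distribution of the per-review
    error component r_r.  The stated masses (0.65, 0.12, 0.13) sum to 0.90; the
    remaining 0.10 is completed at r_r = 0 (a perfectly accurate review).
    The journal error r_j rises linearly with reputation rank from
    ``journal_error_range[0]`` (top journal) to ``journal_error_range[1]``
    (bottom journal); the probability of a competitive reviewer falls linearly
    from ``competitive_prob_range[1]`` at the top to the range minimum at the
    bottom.  The score error is ``score_error_coef * Q``.
    """

    reviewing_error_table: tuple = ((0.65, 0.1), (0.12, 0.05), (0.13, 0.01), (0.10, 0.0))
    journal_error_range: tuple = (0.0, 0.15)
    score_error_coef: float = 0.05
    competitive_prob_range: tuple = (0.10, 0.66)
    competitive_shift_range: tuple = (0.01, 0.05)
    editor_halfwidth: float = 0.1  # Q_e ~ U[(1-h)Q, (1+h)Q]

    def validate(self) -> None:
        total = sum(p for p, _ in self.reviewing_error_table)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"reviewing_error_table masses sum to {total}, expected 1")
        for name in ("journal_error_range", "competitive_prob_range", "competitive_shift_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be (lo, hi) with lo <= hi")
        if self.editor_halfwidth < 0:
            raise ValueError("editor_halfwidth must be >= 0")

    @classmethod
    def zero_noise(cls) -> "ErrorModelParams":
        """All assessment-error sources off: Q_e = Q and Q_r = Q exactly."""
        return cls(
            reviewing_error_table=((1.0, 0.0),),
            journal_error_range=(0.0, 0.0),
            competitive_prob_range=(0.0, 0.0),
            editor_halfwidth=0.0,
        )


@dataclass
class TimingConfig:
    """Stage durations (weeks) and the per-review hours distribution.

    Stand-ins for survey-based duration distributions; each stage is a fixed
    week count by default.  Review hours are log-normal with the given median
    and log-scale sd.
    """

    desk_weeks: int = 2
    review_weeks: int = 6
    revision_weeks: int = 4
    resubmission_gap_weeks: int = 1
    review_hours_median: float = 5.0
    review_hours_log_sd: float = 0.5

    def validate(self) -> None:
        for name in ("desk_weeks", "review_weeks", "revision_weeks", "resubmission_gap_weeks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.review_hours_median <= 0 or self.review_hours_log_sd < 0:
            raise ValueError("invalid review-hours distribution")


@dataclass
class PolicyConfig:
    """Which peer-review system runs, and its variant-specific knobs.

    * ``n_groups`` (N_g): publisher groups for cascade review sharing.
    * ``concordance_alpha`` (α): editor/shared-review agreement threshold
      |Q_e − Q_r| / Q_r ≤ α below which a revision (not fresh reviews) is asked.
    * ``p_cascade_accept`` (P_cas): probability an author accepts the editor's
      cascade proposal on rejection.
    * ``forced_comment_count``: overrides the attracted online-commenter count
      under crowdsourcing (0 reproduces immediate publication exactly).
    * ``crowd_aggregation``: how the editor combines online and invited scores.
    """

    variant: str = "conventional"
    n_groups: int = 4
    concordance_alpha: float = 0.1
    p_cascade_accept: float = 1.0
    forced_comment_count: Optional[int] = None
    crowd_aggregation: str = "weighted_mean"

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if self.concordance_alpha < 0:
            raise ValueError("concordance_alpha must be >= 0")
        if not 0.0 <= self.p_cascade_accept <= 1.0:
            raise ValueError("p_cascade_accept must be in [0, 1]")
        if self.forced_comment_count is not None and self.forced_comment_count < 0:
            raise ValueError("forced_comment_count must be >= 0")
        if self.crowd_aggregation not in AGGREGATIONS:
            raise ValueError(f"unknown crowd_aggregation {self.crowd_aggregation!r}")


@dataclass
class CalibrationConfig:
    """Synthetic journal-ecosystem and researcher-population generator knobs.

    Stands in for the unpublished empirical calibration: reputations are drawn
    from ``reputation_law`` and rescaled into (0, 1]; desk thresholds are
    proportional, t_min = a·reputation, while acceptance thresholds are affine
    with a floor, t_max = acceptance_floor + (b − acceptance_floor)·reputation,
    with (a, b) = ``threshold_offsets`` — post-review acceptance standards vary
    much less across journal tiers than desk standards do, but still fall with
    reputation.  Weekly submission counts are
    N(``weekly_submissions_mean``, ``weekly_submissions_sd``) at the reference
    population of 25,000 researchers and scale linearly with ``n_researchers``.
    """

    n_journals: int = 105
    reputation_law: str = "lognormal_rescaled"
    lognormal_sigma: float = 1.3
    threshold_offsets: tuple = (0.7, 0.8)
    acceptance_floor: float = 0.6
    n_researchers: int = 25_000
    initial_resource_range: tuple = (1.0, 100.0)
    weekly_submissions_mean: float = 850.0
    weekly_submissions_sd: float = 85.0
    reference_population: int = 25_000

    def validate(self) -> None:
        a, b = self.threshold_offsets
        if not (0 < a < b):
            raise ValueError("threshold_offsets must satisfy 0 < a < b")
        if not 0 <= self.acceptance_floor <= b:
            raise ValueError("acceptance_floor must lie in [0, b]")
        if self.n_journals < 6:
            raise ValueError("n_journals must be >= 6 (cascade needs lower-reputation candidates)")
        if self.reputation_law not in REPUTATION_LAWS:
            raise ValueError(f"unknown reputation_law {self.reputation_law!r}")
        lo, hi = self.initial_resource_range
        if not (0 < lo <= hi):
            raise ValueError("initial_resource_range must be positive and ordered")
        if self.n_researchers < 1 or self.reference_population < 1:
            raise ValueError("population sizes must be positive")
        if self.weekly_submissions_mean < 0 or self.weekly_submissions_sd < 0:
            raise ValueError("weekly submission parameters must be >= 0")

    @property
    def submission_scale(self) -> float:
        return self.n_researchers / self.reference_population


@dataclass
class SimulationConfig:
    """Top-level run description: calibration + policy + timings + errors."""

    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    policy: PolicyConfig = field(default_factory=PolicyConfig)
    timing: TimingConfig = field(default_factory=TimingConfig)
    errors: ErrorModelParams = field(default_factory=ErrorModelParams)
    horizon_years: int = 10
    burn_in_years: int = 1
    n_runs: int = 100
    master_seed: int = 0
    q_mean_over: str = "published"  # or "all"
    hellinger_bins: int = 100
    log_individual_events: bool = False  # per-agent growth/reward rows in the log

    def validate(self) -> None:
        self.calibration.validate()
        self.policy.validate()
        self.timing.validate()
        self.errors.validate()
        if not 0 <= self.burn_in_years < self.horizon_years:
            raise ValueError("need 0 <= burn_in_years < horizon_years")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.q_mean_over not in ("published", "all"):
            raise ValueError("q_mean_over must be 'published' or 'all'")
        if self.hellinger_bins < 2:
            raise ValueError("hellinger_bins must be >= 2")

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def test_profile(cls, variant: str = "conventional", **overrides) -> "SimulationConfig":
        """Desk-scale profile: 2,500 researchers, 105 journals, ~85 weekly
        submissions, 3-year horizon with 1-year burn-in, 10 replicate runs."""
        cfg = cls(
            calibration=CalibrationConfig(n_researchers=2_500),
            policy=PolicyConfig(variant=variant),
            horizon_years=3,
            burn_in_years=1,
            n_runs=10,
        )
        return replace(cfg, **overrides) if overrides else cfg

    @property
    def total_weeks(self) -> int:
        return self.horizon_years * 52

    @property
    def burn_in_weeks(self) -> int:
        return self.burn_in_years * 52

    # -- serialisation ------------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        kwargs = {}
        for key, sub in (
            ("calibration", CalibrationConfig),
            ("policy", PolicyConfig),
            ("timing", TimingConfig),
            ("errors", ErrorModelParams),
        ):
            if key in d:
                block = dict(d.pop(key))
                # YAML gives lists where dataclass defaults are tuples
                fields_ = sub.__dataclass_fields__
                for k, v in list(block.items()):
                    if k not in fields_:
                        raise ValueError(f"unknown key {k!r} in config block {key!r}")
                    if isinstance(v, list):
                        block[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                kwargs[key] = sub(**block)
        for k in d:
            if k not in cls.__dataclass_fields__:
                raise ValueError(f"unknown top-level config key {k!r}")
        cfg = cls(**kwargs, **d)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        """Stable hash of the config, recorded in run metadata."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML (or JSON — YAML is a superset) configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
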