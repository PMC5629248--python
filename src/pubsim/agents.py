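"""Core entities and the researcher resource/quality economy.

Researchers hold resources R(t) (the means to do research) and a base
scientific level S_b(t) (accumulated rewards); their scientific level is the
derived sum S(t) = R(t) + S_b(t).  Submitting a manuscript consumes an
investment R_inv ~ U[0.2R, 0.7R]; the investment and the author's level set the
expected quality

    E_Q = 0.8 * 0.1*R_inv / (0.1*R_inv + 1) + 0.2 * 0.01*S / (0.01*S + 1)

and the latent quality score is Q ~ N(E_Q, 0.1*E_Q), truncated at zero by
resampling.  Publication returns a random fraction p ~ U[0, 0.5] of the total
invested resources to both R and S_b; completing a review credits S_b with
U[0, 0.001]; and every week both R and S_b grow by independent U[0.1, 1] draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

__all__ = [
    "Researcher",
    "Manuscript",
    "Journal",
    "ReviewReport",
    "Population",
    "invest_resources",
    "expected_quality",
    "draw_q_score",
    "apply_publication_rewards",
    "apply_reviewer_reward",
    "weekly_growth",
]

STATUSES = ("in_process", "published", "abandoned", "discussion_unindexed")


@dataclass
class Researcher:
    """An author/reviewer agent. ``scientific_level`` is always R + S_b."""

    id: int
    resources: float = 0.0
    base_level: float = 0.0
    active_manuscript: Optional[int] = None

    @property
    def scientific_level(self) -> float:
        return self.resources + self.base_level


@dataclass
class Journal:
    """A journal: reputation in (0, 1] with desk/acceptance thresholds.

    ``reputation_rank_fraction`` is 0 for the highest-reputation journal and 1
    for the lowest; ``ar`` is the acceptance rate among externally reviewed
    papers, estimated from a conventional-system run.
    """

    id: int
    reputation: float
    t_min: float
    t_max: float
    group_id: Optional[int] = None
    ar: Optional[float] = None
    reputation_rank_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.t_min < self.t_max):
            raise ValueError(f"journal {self.id}: need 0 < t_min < t_max")
        if not (0 < self.reputation <= 1):
            raise ValueError(f"journal {self.id}: reputation must be in (0, 1]")


@dataclass
class SubmissionRecord:
    journal_id: int
    week: int
    via: str  # "first" | "conventional" | "cascade"
    decision: Optional[str] = None
    rounds: int = 0


@dataclass
class Manuscript:
    """A manuscript and its full submission/quality history."""

    id: int
    author_id: int
    q_initial: float
    q_current: float
    e_q: float
    r_inv: float
    r_imp_list: List[float] = field(default_factory=list)
    n_submissions: int = 0
    status: str = "in_process"
    history: List[SubmissionRecord] = field(default_factory=list)
    last_shared_review: Optional[float] = None
    si_released: float = 0.0
    first_week: Optional[int] = None
    terminal_week: Optional[int] = None
    published_journal: Optional[int] = None

    @property
    def total_investment(self) -> float:
        return self.r_inv + sum(self.r_imp_list)

    def set_status(self, status: str) -> None:
        if status not in STATUSES:
            raise ValueError(f"unknown status {status!r}")
        if self.status != "in_process":
            raise ValueError(f"manuscript {self.id}: terminal status {self.status} is final")
        self.status = status


@dataclass
class ReviewReport:
    """One reviewer assessment Q_r with its error components and hours spent."""

    manuscript_id: int
    reviewer_id: int
    q_r: float
    error_sd: float
    competitive: bool
    shift: float
    hours: float
    kind: str = "invited"  # or "online"


# ---------------------------------------------------------------------------
# Economy operations
# ---------------------------------------------------------------------------

def invest_resources(researcher: Researcher, rng: np.random.Generator) -> float:
    """Draw the research investment R_inv ~ U[0.2R, 0.7R] and deduct it.

    An agent with no resources cannot invest and skips submission (returns 0).
    """
    r = researcher.resources
    if r <= 0:
        return 0.0
    investment = rng.uniform(0.2 * r, 0.7 * r)
    researcher.resources -= investment
    return investment


def expected_quality(r_inv: float, s_level: float) -> float:
    """Expected quality E_Q of a paper: two saturating terms in [0, 1).

    Weighted 0.8 on invested resources and 0.2 on the author's scientific
    level; strictly increasing in both arguments.
    """
    if r_inv < 0 or s_level < 0:
        raise ValueError("r_inv and s_level must be non-negative")
    x = 0.1 * r_inv
    y = 0.01 * s_level
    return 0.8 * x / (x + 1.0) + 0.2 * y / (y + 1.0)


def draw_q_score(e_q: float, rng: np.random.Generator) -> float:
    """Draw Q ~ N(E_Q, 0.1*E_Q), truncated at zero by resampling."""
    if not 0 <= e_q < 1:
        raise ValueError("e_q must lie in [0, 1)")
    if e_q == 0:
        return 0.0
    sd = 0.1 * e_q
    q = rng.normal(e_q, sd)
    while q <= 0:
        q = rng.normal(e_q, sd)
    return q


def apply_publication_rewards(
    researcher: Researcher, manuscript: Manuscript, rng: np.random.Generator
) -> float:
    """Credit the author on publication: p ~ U[0, 0.5] of all invested
    resources is returned to R, and the same amount is added to S_b."""
    if manuscript.status != "published":
        raise ValueError("publication rewards apply to published manuscripts only")
    p = rng.uniform(0.0, 0.5)
    reward = p * manuscript.total_investment
    researcher.resources += reward
    researcher.base_level += reward
    return reward


def apply_reviewer_reward(researcher: Researcher, rng: np.random.Generator) -> float:
    """Credit a completed review: S_b += U[0, 0.001] (knowledge acquired)."""
    reward = rng.uniform(0.0, 0.001)
    researcher.base_level += reward
    return reward


def weekly_growth(researcher: Researcher, rng: np.random.Generator) -> tuple:
    """End-of-week update: R and S_b each grow by an independent U[0.1, 1]."""
    dr = rng.uniform(0.1, 1.0)
    db = rng.uniform(0.1, 1.0)
    researcher.resources += dr
    researcher.base_level += db
    return dr, db


# ---------------------------------------------------------------------------
# Array-backed population (engine hot path)
# ---------------------------------------------------------------------------

class Population:
    """The researcher population as flat arrays, with object views.

    Weekly growth is applied as two vectorised independent U[0.1, 1] draws per
    agent.  ``view(i)`` returns a Researcher proxy whose mutations write back,
    so per-event operations run through the same economy functions as the
    object-level API.
    """

    def __init__(self, n: int, initial_resource_range: tuple, rng: np.random.Generator):
        lo, hi = initial_resource_range
        self.n = n
        self.resources = rng.uniform(lo, hi, size=n)
        self.base_level = np.zeros(n)
        self.busy = np.zeros(n, dtype=bool)

    def weekly_growth(self, rng: np.random.Generator) -> tuple:
        dr = rng.uniform(0.1, 1.0, size=self.n)
        db = rng.uniform(0.1, 1.0, size=self.n)
        self.resources += dr
        self.base_level += db
        return dr, db

    def idle_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.busy)

    def scientific_level(self, i: int) -> float:
        return float(self.resources[i] + self.base_level[i])

    def view(self, i: int) -> "_ResearcherView":
        return _ResearcherView(self, i)


class _ResearcherView(Researcher):
    """Researcher facade over Population arrays (writes back on mutation)."""

    def __init__(self, pop: Population, i: int):
        self._pop = pop
        self._i = i
        # deliberately not calling dataclass __init__; attributes are properties
        object.__setattr__(self, "id", i)
        object.__setattr__(self, "active_manuscript", None)

    @property
    def resources(self) -> float:  # type: ignore[override]
        return float(self._pop.resources[self._i])

    @resources.setter
    def resources(self, value: float) -> None:
        self._pop.resources[self._i] = value

    @property
    def base_level(self) -> float:  # type: ignore[override]
        return float(self._pop.base_level[self._i])

    @base_level.setter
    def base_level(self, value: float) -> None:
        self._pop.base_level[self._i] = value
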