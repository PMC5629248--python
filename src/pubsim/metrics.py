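"""Outcome measures computed from a run's event log.

Three outcome families compare the systems:

* **peer-review efficiency** — the Hellinger distance between the final
  Q-score distributions of published and unpublished papers (how well review
  separates them), and the relative improvement of the mean Q score after
  revisions versus first submission;
* **reviewer effort** — total reviewing hours per year converted to work-years
  (8 h days, 365 − 104 weekend − 25.3 holiday days per year);
* **scientific dissemination** — annual publications, median weeks from first
  submission to the final decision, the mean Q score of papers and the average
  weekly release of scientific information.

All measures are deterministic, permutation-invariant functions of the log.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .config import SimulationConfig
from .eventlog import EventLog

__all__ = [
    "OutcomeReport",
    "hellinger_distance",
    "relative_q_improvement",
    "reviewer_effort_work_years",
    "dissemination_summary",
    "compute_outcomes",
    "WORKING_HOURS_PER_YEAR",
]

# 8 h/day over (365 − 104 weekend − 25.3 holiday) working days
WORK_HOURS_PER_DAY = 8.0
WORKING_DAYS_PER_YEAR = 365.0 - 104.0 - 25.3
WORKING_HOURS_PER_YEAR = WORK_HOURS_PER_DAY * WORKING_DAYS_PER_YEAR  # 1885.6


@dataclass
class OutcomeReport:
    """The six headline outcome measures for one simulation run."""

    hellinger_published_vs_unpublished: float
    relative_q_improvement: float
    reviewer_effort_work_years: float
    annual_publications: float
    median_weeks_to_final_decision: float
    weekly_si_release: float
    mean_q_published: float = float("nan")
    mean_q_all: float = float("nan")

    def as_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def hellinger_distance(q_published: Sequence[float], q_unpublished: Sequence[float],
                       bins: int = 100) -> float:
    """Histogram Hellinger distance between two samples.

    Both samples are binned on a common grid of ``bins`` equal-width bins
    spanning their joint range; HD = sqrt(1 − Σ sqrt(p_i q_i)) ∈ [0, 1]
    (0 = identical, 1 = disjoint support).
    """
    x = np.asarray(q_published, dtype=float)
    y = np.asarray(q_unpublished, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if lo == hi:  # all mass in one point: identical distributions
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    p = np.histogram(x, bins=edges)[0] / x.size
    q = np.histogram(y, bins=edges)[0] / y.size
    bc = np.sum(np.sqrt(p * q))  # Bhattacharyya coefficient
    return float(np.sqrt(max(0.0, 1.0 - bc)))


def relative_q_improvement(q_initial: Sequence[float], q_final: Sequence[float]) -> float:
    """(mean(Q_final) − mean(Q_initial)) / mean(Q_initial) over the same papers."""
    qi = np.asarray(q_initial, dtype=float)
    qf = np.asarray(q_final, dtype=float)
    if qi.size == 0 or qf.size != qi.size:
        raise ValueError("need equally sized, non-empty paired samples")
    mi = qi.mean()
    return float((qf.mean() - mi) / mi)


def reviewer_effort_work_years(total_review_hours: float) -> float:
    """Convert reviewing hours to work-years: hours / 1885.6."""
    if total_review_hours < 0:
        raise ValueError("total_review_hours must be >= 0")
    return total_review_hours / WORKING_HOURS_PER_YEAR


def _analysis_cohort(log: EventLog, burn_in_weeks: int):
    """Manuscripts first submitted after burn-in that reached a terminal state."""
    return [ms for ms in log.manuscripts.values()
            if ms.first_week is not None and ms.first_week >= burn_in_weeks
            and ms.status != "in_process"]


def dissemination_summary(log: EventLog, burn_in_weeks: int,
                          total_weeks: int) -> Tuple[float, float, float, float]:
    """(annual publications, median weeks to final decision, mean Q of all
    terminal papers, mean weekly SI release), burn-in excluded.

    Publications and SI are flow measures over post-burn-in weeks; the median
    decision time and mean Q are cohort measures over manuscripts first
    submitted after burn-in.
    """
    n_weeks = total_weeks - burn_in_weeks
    if n_weeks <= 0:
        raise ValueError("total_weeks must exceed burn_in_weeks")
    years = n_weeks / 52.0
    n_pubs = sum(1 for w, *_ in log.publications if burn_in_weeks <= w < total_weeks)
    annual_publications = n_pubs / years
    si_total = sum(a for w, _, a in log.si_ledger if burn_in_weeks <= w < total_weeks)
    weekly_si = si_total / n_weeks
    cohort = _analysis_cohort(log, burn_in_weeks)
    if cohort:
        times = [ms.terminal_week - ms.first_week for ms in cohort]
        median_weeks = float(np.median(times))
        mean_q_all = float(np.mean([ms.q_current for ms in cohort]))
    else:
        median_weeks = float("nan")
        mean_q_all = float("nan")
    return annual_publications, median_weeks, mean_q_all, weekly_si


def compute_outcomes(log: EventLog, config: SimulationConfig) -> OutcomeReport:
    """Assemble the full outcome report for one run."""
    burn_in = config.burn_in_weeks
    total = config.total_weeks
    years = (total - burn_in) / 52.0

    cohort = _analysis_cohort(log, burn_in)
    published = [ms for ms in cohort if ms.status == "published"]
    unpublished = [ms for ms in cohort if ms.status in ("abandoned", "discussion_unindexed")]

    if published and unpublished:
        hd = hellinger_distance([ms.q_current for ms in published],
                                [ms.q_current for ms in unpublished],
                                bins=config.hellinger_bins)
    else:
        hd = float("nan")
    if cohort:
        improvement = relative_q_improvement([ms.q_initial for ms in cohort],
                                             [ms.q_current for ms in cohort])
    else:
        improvement = float("nan")

    hours = sum(h for w, _, _, _, h, _ in log.reviews if burn_in <= w < total)
    effort = reviewer_effort_work_years(hours) / years

    annual_pubs, median_weeks, mean_q_all, weekly_si = dissemination_summary(
        log, burn_in, total)
    mean_q_pub = float(np.mean([ms.q_current for ms in published])) if published else float("nan")

    return OutcomeReport(
        hellinger_published_vs_unpublished=hd,
        relative_q_improvement=improvement,
        reviewer_effort_work_years=effort,
        annual_publications=annual_pubs,
        median_weeks_to_final_decision=median_weeks,
        weekly_si_release=weekly_si,
        mean_q_published=mean_q_pub,
        mean_q_all=mean_q_all,
    )
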