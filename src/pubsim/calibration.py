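"""Synthetic calibration: journal ecosystem, submitter sampling, AR estimation.

The empirical calibration the model was originally fitted to (rescaled impact
factors of 105 journals, survey-based durations) is not available, so this
module generates a configurable synthetic stand-in: reputations drawn from a
skewed law and rescaled into (0, 1], with desk/acceptance thresholds
proportional to reputation (t_min = a*rep, t_max = b*rep, a < b).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .agents import Journal
from .config import CalibrationConfig

__all__ = [
    "generate_journals",
    "JournalEcosystem",
    "estimate_ar",
    "sample_weekly_submitters",
    "journals_to_csv",
    "journals_from_csv",
]


def generate_journals(config: CalibrationConfig, rng: np.random.Generator) -> List[Journal]:
    """Generate the journal ecosystem.

    Reputations are drawn from the configured law (log-normal by default — a
    heavy right tail mimicking impact-factor skew), rescaled so the maximum is
    exactly 1, then sorted descending to define ``reputation_rank_fraction``
    (0 = highest reputation, 1 = lowest).  The desk threshold is proportional,
    t_min = a*reputation; the acceptance threshold is affine,
    t_max = floor + (b - floor)*reputation, rising from ``acceptance_floor``
    at the bottom of the ecosystem to b at the top.
    """
    config.validate()
    j = config.n_journals
    if config.reputation_law == "lognormal_rescaled":
        raw = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=j)
    else:  # uniform
        raw = rng.uniform(0.0, 1.0, size=j)
        raw = np.where(raw == 0, np.finfo(float).tiny, raw)
    reputations = raw / raw.max()  # into (0, 1], max exactly 1
    order = np.argsort(-reputations, kind="stable")
    a, b = config.threshold_offsets
    journals = []
    denom = max(j - 1, 1)
    for rank, idx in enumerate(order):
        rep = float(reputations[idx])
        journals.append(
            Journal(
                id=rank,
                reputation=rep,
                t_min=a * rep,
                t_max=config.acceptance_floor + (b - config.acceptance_floor) * rep,
                reputation_rank_fraction=rank / denom,
            )
        )
    return journals


class JournalEcosystem:
    """Journals plus precomputed arrays for fast window/threshold queries.

    Journals are held in descending reputation order.  ``by_tmin_*`` gives the
    t_min values in ascending order together with the owning journal index, so
    targeting-window queries are two binary searches.
    """

    def __init__(self, journals: Sequence[Journal]):
        if not journals:
            raise ValueError("ecosystem needs at least one journal")
        self.journals: List[Journal] = sorted(journals, key=lambda j: -j.reputation)
        self.n = len(self.journals)
        tmins = np.array([j.t_min for j in self.journals])
        self._tmin_order = np.argsort(tmins, kind="stable")
        self._tmin_sorted = tmins[self._tmin_order]
        self._group_members: Optional[Dict[int, List[int]]] = None

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.journals)

    def __getitem__(self, i: int) -> Journal:
        return self.journals[i]

    def in_tmin_window(self, lo: float, hi: float) -> np.ndarray:
        """Indices (into reputation order) of journals with t_min in [lo, hi]."""
        left = np.searchsorted(self._tmin_sorted, lo, side="left")
        right = np.searchsorted(self._tmin_sorted, hi, side="right")
        return self._tmin_order[left:right]

    def nearest_tmin(self, value: float) -> int:
        """Journal index whose t_min is closest to ``value`` (fallback rule)."""
        pos = np.searchsorted(self._tmin_sorted, value)
        cands = [p for p in (pos - 1, pos) if 0 <= p < self.n]
        best = min(cands, key=lambda p: abs(self._tmin_sorted[p] - value))
        return int(self._tmin_order[best])

    def rebuild_groups(self) -> None:
        """Index group membership (descending reputation within each group)."""
        members: Dict[int, List[int]] = {}
        for idx, j in enumerate(self.journals):
            if j.group_id is not None:
                members.setdefault(j.group_id, []).append(idx)
        self._group_members = members

    def group_members(self, group_id: int) -> List[int]:
        if self._group_members is None:
            self.rebuild_groups()
        return self._group_members.get(group_id, [])  # type: ignore[union-attr]


def estimate_ar(conventional_log, journal_ids: Optional[Sequence[int]] = None) -> Dict[int, float]:
    """Per-journal acceptance rate after desk screening, AR_j.

    Counts, from a conventional-system run log, the submissions sent to
    external review at each journal and the acceptances among them.  Journals
    that never reviewed a paper get the ecosystem mean (fallback).
    """
    reviewed: Dict[int, int] = {}
    accepted: Dict[int, int] = {}
    n_rows = 0
    for week, ms_id, journal_id, kind, rnd in conventional_log.decisions:
        n_rows += 1
        if kind == "sent_to_review":
            reviewed[journal_id] = reviewed.get(journal_id, 0) + 1
        elif kind == "accept":
            accepted[journal_id] = accepted.get(journal_id, 0) + 1
    if n_rows == 0:
        raise ValueError("cannot estimate AR_j from an empty event log")
    rates = {j: accepted.get(j, 0) / n for j, n in reviewed.items() if n > 0}
    if not rates:
        raise ValueError("no externally reviewed submissions in log")
    mean_rate = sum(rates.values()) / len(rates)
    if journal_ids is None:
        journal_ids = sorted({j for _, _, j, _, _ in conventional_log.decisions})
    return {j: rates.get(j, mean_rate) for j in journal_ids}


def sample_weekly_submitters(
    idle: np.ndarray, config: CalibrationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Sample this week's submitting researchers among the idle ones.

    The count is a N(mean, sd) draw scaled linearly by the population ratio
    n_researchers / 25,000, rounded and clipped to [0, #idle]; the subset is
    uniform without replacement.
    """
    scale = config.submission_scale
    n_s = int(round(rng.normal(config.weekly_submissions_mean * scale,
                               config.weekly_submissions_sd * scale)))
    n_s = max(0, min(n_s, idle.size))
    if n_s == 0:
        return np.empty(0, dtype=idle.dtype)
    return rng.choice(idle, size=n_s, replace=False)


# ---------------------------------------------------------------------------
# CSV replay of a generated ecosystem
# ---------------------------------------------------------------------------

_CSV_FIELDS = ["id", "reputation", "t_min", "t_max", "group_id", "ar", "reputation_rank_fraction"]


def journals_to_csv(journals: Sequence[Journal], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for j in journals:
            writer.writerow({
                "id": j.id, "reputation": repr(j.reputation), "t_min": repr(j.t_min),
                "t_max": repr(j.t_max), "group_id": "" if j.group_id is None else j.group_id,
                "ar": "" if j.ar is None else repr(j.ar),
                "reputation_rank_fraction": repr(j.reputation_rank_fraction),
            })


def journals_from_csv(path: str | Path) -> List[Journal]:
    journals = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            journals.append(Journal(
                id=int(row["id"]),
                reputation=float(row["reputation"]),
                t_min=float(row["t_min"]),
                t_max=float(row["t_max"]),
                group_id=int(row["group_id"]) if row["group_id"] else None,
                ar=float(row["ar"]) if row["ar"] else None,
                reputation_rank_fraction=float(row["reputation_rank_fraction"]),
            ))
    return journals
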