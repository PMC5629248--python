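"""Run event log: compact in-memory ledgers plus JSONL export.

Every review, decision, SI release and publication appears exactly once, so
all outcome measures are recomputable offline from the log alone.  Rows are
plain tuples (week first) appended in simulation order; ``write_jsonl`` streams
them as one JSON object per line.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .agents import Manuscript

__all__ = ["EventLog", "write_jsonl"]

# row layouts (week first, ids then payload)
# reviews:      (week, manuscript_id, journal_id, reviewer_id, hours, kind)
# decisions:    (week, manuscript_id, journal_id, kind, round)
# si_ledger:    (week, manuscript_id, amount)
# publications: (week, manuscript_id, journal_id, q_final)
# rewards:      (week, researcher_id, kind, amount)          [optional]
# growth:       (week, researcher_id, d_resources, d_base)   [optional]


@dataclass
class EventLog:
    manuscripts: Dict[int, Manuscript] = field(default_factory=dict)
    reviews: List[Tuple] = field(default_factory=list)
    decisions: List[Tuple] = field(default_factory=list)
    si_ledger: List[Tuple] = field(default_factory=list)
    publications: List[Tuple] = field(default_factory=list)
    rewards: List[Tuple] = field(default_factory=list)
    growth: List[Tuple] = field(default_factory=list)

    # -- views ---------------------------------------------------------------
    def reviews_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.reviews, columns=[
            "week", "manuscript_id", "journal_id", "reviewer_id", "hours", "kind"])

    def decisions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.decisions, columns=[
            "week", "manuscript_id", "journal_id", "kind", "round"])

    def si_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.si_ledger, columns=["week", "manuscript_id", "amount"])

    def publications_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.publications, columns=[
            "week", "manuscript_id", "journal_id", "q_final"])

    def manuscript_si_totals(self) -> Dict[int, float]:
        totals: Dict[int, float] = {}
        for week, ms_id, amount in self.si_ledger:
            totals[ms_id] = totals.get(ms_id, 0.0) + amount
        return totals

    # -- provenance ------------------------------------------------------------
    def digest(self) -> str:
        """Content hash over every ledger, for determinism checks."""
        h = hashlib.sha256()
        for rows in (self.reviews, self.decisions, self.si_ledger,
                     self.publications, self.rewards, self.growth):
            for row in rows:
                h.update(repr(row).encode())
        for ms_id in sorted(self.manuscripts):
            ms = self.manuscripts[ms_id]
            h.update(repr((ms.id, ms.status, ms.q_initial, ms.q_current,
                           ms.n_submissions, ms.first_week, ms.terminal_week,
                           ms.si_released)).encode())
        return h.hexdigest()


def _iter_events(log: EventLog):
    for week, ms, j, rev, hours, kind in log.reviews:
        yield {"week": week, "type": "review", "manuscript": ms, "journal": j,
               "reviewer": rev, "hours": hours, "kind": kind}
    for week, ms, j, kind, rnd in log.decisions:
        yield {"week": week, "type": "decision", "manuscript": ms, "journal": j,
               "kind": kind, "round": rnd}
    for week, ms, amount in log.si_ledger:
        yield {"week": week, "type": "si_release", "manuscript": ms, "amount": amount}
    for week, ms, j, q_f in log.publications:
        yield {"week": week, "type": "publication", "manuscript": ms, "journal": j,
               "q_final": q_f}
    for week, res, kind, amount in log.rewards:
        yield {"week": week, "type": "reward", "researcher": res, "kind": kind,
               "amount": amount}
    for week, res, dr, db in log.growth:
        yield {"week": week, "type": "growth", "researcher": res,
               "d_resources": dr, "d_base": db}


def write_jsonl(log: EventLog, path: str | Path) -> None:
    """Stream the log as JSONL, events sorted by week (type order stable)."""
    events = sorted(_iter_events(log), key=lambda e: e["week"])
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev) + "\n")
        for ms_id in sorted(log.manuscripts):
            ms = log.manuscripts[ms_id]
            fh.write(json.dumps({
                "type": "manuscript", "id": ms.id, "author": ms.author_id,
                "status": ms.status, "q_initial": ms.q_initial,
                "q_current": ms.q_current, "n_submissions": ms.n_submissions,
                "first_week": ms.first_week, "terminal_week": ms.terminal_week,
                "si_released": ms.si_released,
            }) + "\n")
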