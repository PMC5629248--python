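"""Operations specific to the five alternative peer-review systems.

* **Re-review opt-out (rro)** — at most one external round: after a major
  revision the editor alone judges the revised score.
* **Cascade** — journals form publisher groups; rejected manuscripts move,
  with their last review, to one of the next five lower-reputation journals of
  the same group, where a triage rule decides between immediate acceptance,
  an editor-judged revision, or fresh reviews.
* **Portable** — the same review-sharing triage, but resubmission targets any
  journal (the conventional targeting rule).
* **Crowdsourcing** — manuscripts passing desk screening are posted as
  discussion papers, releasing initial scientific information AR_j·Q and
  attracting online commenters whose scores are blended with the invited
  reviews in a single decision round.
* **Immediate publication** — the crowdsourcing pathway with zero online
  commenters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .agents import Journal, Manuscript, ReviewReport
from .calibration import JournalEcosystem
from .conventional import DecisionOutcome, editor_assessment

__all__ = [
    "CrowdContext",
    "rro_final_decision",
    "allocate_groups",
    "cascade_select_journal",
    "shared_review_triage",
    "cascade_resubmission_probability",
    "initial_scientific_information",
    "n_online_commenters",
    "crowd_decision",
    "release_remaining_si",
]

CASCADE_HOP_CANDIDATES = 5  # "one of the next five journals of lower reputation"
ABANDONED_SI_RETAINED = 0.2  # rejected, never resubmitted: SI = 0.2 * SI_init


@dataclass
class CrowdContext:
    """Per-week crowdsourcing bookkeeping for one discussion paper."""

    si_init: float
    mean_si_total: float
    n_online: int = 0
    online_reports: List[ReviewReport] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.si_init < 0 or self.n_online < 0:
            raise ValueError("si_init and n_online must be non-negative")


def rro_final_decision(q_revised: float, journal: Journal,
                       rng: np.random.Generator, halfwidth: float = 0.1) -> DecisionOutcome:
    """Re-review opt-out: the editor assesses the revised manuscript,
    Q_e ~ U[0.9·Q_revised, 1.1·Q_revised], and accepts iff Q_e ≥ T_max.
    No second external round ever occurs."""
    q_e = float(editor_assessment(q_revised, rng, halfwidth))
    kind = "accept" if q_e >= journal.t_max else "reject"
    return DecisionOutcome(kind, q_e, round=2)


def allocate_groups(journals: Sequence[Journal], n_groups: int,
                    rng: np.random.Generator) -> List[int]:
    """Assign each journal independently to one of N_g publisher groups.

    For the default N_g = 4 the group probabilities are three N(0.25, 0.025)
    draws with the remainder on the fourth; for other N_g (sensitivity runs)
    the first N_g − 1 are N(1/N_g, 0.1/N_g) with the remainder on the last.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if n_groups == 4:
        mu, sd = 0.25, 0.025
    else:
        mu, sd = 1.0 / n_groups, 0.1 / n_groups
    for _ in range(100):
        head = rng.normal(mu, sd, size=n_groups - 1)
        probs = np.append(head, 1.0 - head.sum())
        if np.all(probs > 0) and np.all(probs < 1):
            break
    else:
        raise ValueError("could not draw valid group probabilities in 100 attempts")
    assignment = rng.choice(n_groups, size=len(journals), p=probs)
    for j, g in zip(journals, assignment):
        j.group_id = int(g)
    return [int(g) for g in assignment]


def cascade_select_journal(current_journal: Journal, eco: JournalEcosystem,
                           rng: np.random.Generator) -> Optional[int]:
    """Cascade hop: uniform pick among the next (up to) five lower-reputation
    journals of the same group; ``None`` when the group has none below."""
    if current_journal.group_id is None:
        raise ValueError("cascade requires group-allocated journals")
    members = eco.group_members(current_journal.group_id)  # descending reputation
    lower = [i for i in members if eco[i].reputation < current_journal.reputation]
    if not lower:
        return None
    candidates = lower[:CASCADE_HOP_CANDIDATES]
    return int(candidates[rng.integers(len(candidates))])


def shared_review_triage(q_prev_review: float, q: float, journal: Journal,
                         alpha: float, rng: np.random.Generator,
                         editor_halfwidth: float = 0.1) -> Tuple[str, Optional[float]]:
    """Editor triage of a resubmission arriving with its last review Q_r.

    * Q_r ≥ T_max → ``immediate_accept`` (no further reviews).
    * Otherwise draw Q_e ~ U[0.9Q, 1.1Q]; concordant (|Q_e − Q_r|/Q_r ≤ α) →
      ``revise_then_editor``; discordant → ``fresh_reviews``.

    Returns (verdict, q_e) with q_e None on immediate acceptance.
    """
    if q_prev_review <= 0:
        raise ValueError("q_prev_review must be positive")
    if q_prev_review >= journal.t_max:
        return "immediate_accept", None
    q_e = float(editor_assessment(q, rng, editor_halfwidth))
    if abs(q_e - q_prev_review) / q_prev_review <= alpha:
        return "revise_then_editor", q_e
    return "fresh_reviews", q_e


def cascade_resubmission_probability(n_submissions: int) -> float:
    """P_res = 0.88^((N_sub − 1)/2): review-sharing systems resubmit more
    readily (applies to cascade and portable)."""
    if n_submissions < 1:
        raise ValueError("n_submissions must be >= 1")
    return 0.88 ** ((n_submissions - 1) / 2.0)


def initial_scientific_information(journal: Journal, q: float) -> float:
    """SI released when a discussion paper is posted: SI_init = AR_j · Q."""
    if journal.ar is None:
        raise ValueError(f"journal {journal.id} has no AR_j (run the calibration pass first)")
    return journal.ar * q


def n_online_commenters(si_init: float, mean_si_total: float) -> int:
    """Online commenters attracted: round(SI_init / mean(SI_total)^2),
    half-up rounding."""
    if mean_si_total <= 0:
        raise ValueError("mean_si_total must be positive")
    return int(math.floor(si_init / mean_si_total**2 + 0.5))


def crowd_decision(online_reports: Sequence[ReviewReport],
                   invited_reports: Sequence[ReviewReport],
                   n_invited: int, aggregation: str,
                   rng: np.random.Generator) -> float:
    """Editor's decision score under crowdsourcing.

    ``weighted_mean`` (default): Q_r = (Q_online + n·Q_invited)/(n + 1), with
    Q_invited a uniformly picked invited report and Q_online the mean online
    score; no online comments → Q_r = Q_invited.  ``average_all`` takes the
    unweighted mean of every report; ``random_pick`` a uniform pick among all.
    """
    if not invited_reports:
        raise ValueError("crowd decision requires at least one invited report")
    if aggregation == "average_all":
        scores = [r.q_r for r in invited_reports] + [r.q_r for r in online_reports]
        return float(np.mean(scores))
    if aggregation == "random_pick":
        all_reports = list(invited_reports) + list(online_reports)
        return all_reports[rng.integers(len(all_reports))].q_r
    if aggregation != "weighted_mean":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    q_invited = invited_reports[rng.integers(len(invited_reports))].q_r
    if not online_reports:
        return q_invited
    q_online = float(np.mean([r.q_r for r in online_reports]))
    return (q_online + n_invited * q_invited) / (n_invited + 1)


def release_remaining_si(manuscript: Manuscript, journal: Optional[Journal]) -> float:
    """Terminal SI ledger event for a discussion paper.

    Accepted: the rest of the information, IF_j·Q_F − SI_init (signed — may be
    negative when AR_j·Q exceeded IF_j·Q_F).  Abandoned after posting: 80 % of
    SI_init is withdrawn, leaving a lifetime total of 0.2·SI_init.  Never
    posted: nothing.
    """
    if manuscript.status == "published":
        if journal is None:
            raise ValueError("published manuscript needs its journal")
        return journal.reputation * manuscript.q_current - manuscript.si_released
    if manuscript.status == "discussion_unindexed":
        return -(1.0 - ABANDONED_SI_RETAINED) * manuscript.si_released
    return 0.0
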