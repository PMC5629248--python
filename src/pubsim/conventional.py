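"""The conventional submission → desk screening → two-round review process.

Editorial and reviewer assessments are noisy functions of the latent quality
score Q.  The editor's desk assessment is Q_e ~ U[0.9Q, 1.1Q]; a manuscript
with Q_e < T_min is desk-rejected, otherwise 2 or 3 reviewers are invited.
Each reviewer reports Q_r ~ N(Q − c, r·Q), where r = r_r + r_j − 0.05Q combines
a per-review error, a journal-prestige error and a score-dependent correction,
and c is a competitive down-shift appearing with probability rising with
journal reputation.  One report, picked uniformly, stands for the editor's
opinion: accept at Q_r ≥ T_max, reject below T_min, ask for a major revision in
between; revised manuscripts get exactly one further round and are accepted
only at Q_r ≥ T_max.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .agents import Journal, Manuscript, Researcher, ReviewReport, draw_q_score, expected_quality
from .calibration import JournalEcosystem
from .config import ErrorModelParams

__all__ = [
    "DecisionOutcome",
    "select_first_journal",
    "editor_assessment",
    "desk_decision",
    "reviewer_assessment",
    "first_round_decision",
    "revise_manuscript",
    "second_round_decision",
    "resubmission_probability",
    "select_resubmission_journal",
    "draw_review_hours",
    "review_episode",
]

RESUBMISSION_CENTRE = 0.22  # resubmissions target T_min near 0.22 * initial Q


@dataclass
class DecisionOutcome:
    kind: str  # "desk_reject" | "accept" | "reject" | "major_revision"
    deciding_q: float
    round: int = 1


def _targeting_epsilon(q: float, rng: np.random.Generator) -> float:
    """Window width ε = 2·x with x ~ N(Q/5, Q/20), resampled until positive."""
    eps = 2.0 * rng.normal(q / 5.0, q / 20.0)
    while eps <= 0:
        eps = 2.0 * rng.normal(q / 5.0, q / 20.0)
    return eps


def _pick_in_window(eco: JournalEcosystem, lo: float, hi: float,
                    centre: float, rng: np.random.Generator) -> int:
    idx = eco.in_tmin_window(lo, hi)
    if idx.size == 0:
        return eco.nearest_tmin(centre)  # fallback: closest journal standard
    return int(idx[rng.integers(idx.size)])


def select_first_journal(q: float, eco: JournalEcosystem, rng: np.random.Generator) -> int:
    """First-submission targeting: a uniform pick among journals with T_min in
    the asymmetric window [Q − 0.45ε, Q + 0.55ε] (a slight high-targeting
    tilt); if no journal qualifies, the nearest-T_min journal."""
    if q <= 0:
        raise ValueError("q must be positive")
    eps = _targeting_epsilon(q, rng)
    return _pick_in_window(eco, q - 0.45 * eps, q + 0.55 * eps, q, rng)


def select_resubmission_journal(q_initial: float, eco: JournalEcosystem,
                                rng: np.random.Generator) -> int:
    """After a rejection authors aim lower: uniform pick among journals with
    T_min in the symmetric window 0.22·Q ± 0.5ε, Q being the INITIAL score."""
    if q_initial <= 0:
        raise ValueError("q_initial must be positive")
    eps = _targeting_epsilon(q_initial, rng)
    centre = RESUBMISSION_CENTRE * q_initial
    return _pick_in_window(eco, centre - 0.5 * eps, centre + 0.5 * eps, centre, rng)


def editor_assessment(q: float, rng: np.random.Generator,
                      halfwidth: float = 0.1, size: Optional[int] = None):
    """Editor's assessment Q_e ~ U[(1−h)Q, (1+h)Q] (default h = 0.1)."""
    if q < 0:
        raise ValueError("q must be non-negative")
    return rng.uniform((1.0 - halfwidth) * q, (1.0 + halfwidth) * q, size=size)


def desk_decision(q_e: float, journal: Journal,
                  rng: np.random.Generator) -> Tuple[DecisionOutcome, int]:
    """Desk screening: reject iff Q_e < T_min, otherwise send to 2 or 3
    reviewers (equal probability).  Returns (outcome, n_reviewers)."""
    if q_e < journal.t_min:
        return DecisionOutcome("desk_reject", q_e, round=0), 0
    n_reviewers = int(rng.integers(2, 4))
    return DecisionOutcome("sent_to_review", q_e, round=0), n_reviewers


def journal_error(journal: Journal, params: ErrorModelParams) -> float:
    """r_j: linear in reputation rank, 0 at the top journal, 0.15 at the bottom."""
    lo, hi = params.journal_error_range
    return lo + (hi - lo) * journal.reputation_rank_fraction


def competitive_probability(journal: Journal, params: ErrorModelParams) -> float:
    """P(competitive reviewer): linear in rank, highest at the top journal."""
    lo, hi = params.competitive_prob_range
    return lo + (hi - lo) * (1.0 - journal.reputation_rank_fraction)


def draw_review_hours(rng: np.random.Generator, median: float = 5.0,
                      log_sd: float = 0.5) -> float:
    """Hours spent on one report: log-normal with the given median."""
    return float(rng.lognormal(np.log(median), log_sd))


def reviewer_assessment(
    q: float,
    journal: Journal,
    params: ErrorModelParams,
    rng: np.random.Generator,
    manuscript_id: int = -1,
    reviewer_id: int = -1,
    kind: str = "invited",
    hours: Optional[float] = None,
) -> ReviewReport:
    """One reviewer's report: Q_r ~ N(Q − c, r·Q) truncated at zero.

    r = r_r + r_j − 0.05·Q (floored at 0), with r_r from the categorical
    reviewing-error table and r_j set by journal prestige; a competitive
    reviewer shifts the mean down by c ~ U[0.01, 0.05].
    """
    if q <= 0:
        raise ValueError("q must be positive")
    probs, values = zip(*params.reviewing_error_table)
    r_r = values[rng.choice(len(values), p=probs)] if len(values) > 1 else values[0]
    r_j = journal_error(journal, params)
    r = max(r_r + r_j - params.score_error_coef * q, 0.0)
    competitive = rng.uniform() < competitive_probability(journal, params)
    c = rng.uniform(*params.competitive_shift_range) if competitive else 0.0
    sd = r * q
    if sd > 0:
        q_r = rng.normal(q - c, sd)
        tries = 0
        while q_r <= 0:
            q_r = rng.normal(q - c, sd)
            tries += 1
            if tries > 1000:  # pathological: mean far below 0
                q_r = abs(q_r) or np.finfo(float).tiny
                break
    else:
        q_r = max(q - c, np.finfo(float).tiny)
    if hours is None:
        hours = draw_review_hours(rng)
    return ReviewReport(
        manuscript_id=manuscript_id, reviewer_id=reviewer_id, q_r=float(q_r),
        error_sd=sd, competitive=competitive, shift=c, hours=hours, kind=kind,
    )


def first_round_decision(reports: Sequence[ReviewReport], journal: Journal,
                         rng: np.random.Generator) -> DecisionOutcome:
    """Pick one report uniformly as the editor's proxy: accept at
    Q_r ≥ T_max, reject below T_min, major revision in between (revision wins
    at the T_min boundary)."""
    if len(reports) < 2:
        raise ValueError("first-round decision needs at least 2 reports")
    q_r = reports[rng.integers(len(reports))].q_r
    if q_r >= journal.t_max:
        return DecisionOutcome("accept", q_r, round=1)
    if q_r < journal.t_min:
        return DecisionOutcome("reject", q_r, round=1)
    return DecisionOutcome("major_revision", q_r, round=1)


def second_round_decision(reports: Sequence[ReviewReport], journal: Journal,
                          rng: np.random.Generator) -> DecisionOutcome:
    """Re-evaluation of a revised manuscript: accept only at Q_r ≥ T_max."""
    if not reports:
        raise ValueError("second-round decision needs at least 1 report")
    q_r = reports[rng.integers(len(reports))].q_r
    kind = "accept" if q_r >= journal.t_max else "reject"
    return DecisionOutcome(kind, q_r, round=2)


def revise_manuscript(manuscript: Manuscript, researcher: Researcher,
                      rng: np.random.Generator, s_level: Optional[float] = None) -> float:
    """Major revision: invest R_imp ~ N(8/60, 1/60)·R (truncated at 0, R the
    author's current resources), recompute E_Q from the cumulative investment
    and redraw the Q score.  With no resources the revision is a no-op."""
    r = researcher.resources
    if r <= 0:
        return 0.0
    if s_level is None:
        s_level = researcher.scientific_level  # S at revision time, pre-deduction
    f = rng.normal(8.0 / 60.0, 1.0 / 60.0)
    if f < 0:
        f = 0.0
    r_imp = f * r
    researcher.resources -= r_imp
    manuscript.r_imp_list.append(r_imp)
    manuscript.e_q = expected_quality(manuscript.total_investment, s_level)
    manuscript.q_current = draw_q_score(manuscript.e_q, rng)
    return r_imp


def resubmission_probability(n_submissions: int) -> float:
    """P_res = 0.88^(N_sub − 1): the will to resubmit decays with rejections."""
    if n_submissions < 1:
        raise ValueError("n_submissions must be >= 1")
    return 0.88 ** (n_submissions - 1)


def review_episode(
    q: float,
    journal: Journal,
    params: ErrorModelParams,
    rng: np.random.Generator,
    researcher: Optional[Researcher] = None,
    manuscript: Optional[Manuscript] = None,
) -> DecisionOutcome:
    """Run one full adjudication at a single journal, ignoring timing: desk
    screening, first review round and — after a major revision — the second
    round.  Convenience for analyses and small-instance checks; the weekly
    engine interleaves the same operations over time."""
    q_e = float(editor_assessment(q, rng, params.editor_halfwidth))
    outcome, n_rev = desk_decision(q_e, journal, rng)
    if outcome.kind == "desk_reject":
        return outcome
    reports = [reviewer_assessment(q, journal, params, rng) for _ in range(n_rev)]
    decision = first_round_decision(reports, journal, rng)
    if decision.kind != "major_revision":
        return decision
    if researcher is not None and manuscript is not None:
        revise_manuscript(manuscript, researcher, rng)
        q = manuscript.q_current
    reports2 = [reviewer_assessment(q, journal, params, rng) for _ in range(n_rev)]
    return second_round_decision(reports2, journal, rng)
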