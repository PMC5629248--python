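"""Weekly-step simulation engine, replication management and sweeps.

One run is fully determined by (config, seed): a single RNG stream drives the
whole simulation and events are processed in a fixed order.  Each week:
population growth, then the week's new submissions, then every due editorial
event (desk screenings, review rounds, revisions, triages, indexations) in the
order it was scheduled, with rewards and SI releases applied as the events
fire.  Crowdsourcing desk-passes are finalised together at the end of the
week's event pass because the attracted-commenter count depends on that week's
mean initial scientific information.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import conventional as conv
from . import policies as pol
from .agents import (Journal, Manuscript, Population, SubmissionRecord,
                     apply_publication_rewards, apply_reviewer_reward,
                     draw_q_score, expected_quality, invest_resources)
from .calibration import (JournalEcosystem, estimate_ar, generate_journals,
                          sample_weekly_submitters)
from .config import PolicyConfig, SimulationConfig
from .eventlog import EventLog
from .metrics import OutcomeReport, compute_outcomes

__all__ = ["Simulation", "RunResult", "run_simulation", "replicate", "compare", "sweep"]

OUTCOME_COLUMNS = [
    "hellinger_published_vs_unpublished", "relative_q_improvement",
    "reviewer_effort_work_years", "annual_publications",
    "median_weeks_to_final_decision", "weekly_si_release",
    "mean_q_published", "mean_q_all",
]


@dataclass
class RunResult:
    outcome: OutcomeReport
    log: EventLog
    seed_used: object
    config_digest: str
    ar_table: Optional[Dict[int, float]] = None


def _crowd_equivalent(policy: PolicyConfig) -> PolicyConfig:
    """Immediate publication is the crowdsourcing pathway with 0 commenters."""
    if policy.variant == "immediate":
        return replace(policy, variant="crowdsourcing", forced_comment_count=0)
    return policy


class Simulation:
    """One seeded run of one peer-review system."""

    def __init__(self, config: SimulationConfig, seed=None,
                 journals: Optional[Sequence[Journal]] = None,
                 ar_table: Optional[Dict[int, float]] = None):
        config.validate()
        self.config = config
        self.policy = _crowd_equivalent(config.policy)
        self.variant = self.policy.variant
        self.seed_used = config.master_seed if seed is None else seed
        self.rng = np.random.default_rng(self.seed_used)

        if journals is None:
            journals = generate_journals(config.calibration, self.rng)
        self.eco = JournalEcosystem(journals)
        if self.variant == "cascade":
            pol.allocate_groups(self.eco.journals, self.policy.n_groups, self.rng)
            self.eco.rebuild_groups()
        if self.variant == "crowdsourcing":
            if ar_table is None and any(j.ar is None for j in self.eco):
                raise ValueError(
                    "crowdsourcing/immediate need per-journal AR_j; run a "
                    "conventional calibration first (run_simulation does this "
                    "automatically) or supply ar_table")
            if ar_table is not None:
                mean_ar = sum(ar_table.values()) / len(ar_table)
                for j in self.eco:
                    j.ar = ar_table.get(j.id, mean_ar)

        self.pop = Population(config.calibration.n_researchers,
                              config.calibration.initial_resource_range, self.rng)
        self.log = EventLog()
        self._schedule: Dict[int, List[Tuple[str, int, dict]]] = {}
        self._next_ms_id = 0
        self._week = 0
        self._crowd_passers: List[Tuple[Manuscript, int, float]] = []

    # ------------------------------------------------------------------ utils
    def _at(self, week: int, kind: str, ms_id: int, payload: dict) -> None:
        if week < self.config.total_weeks:
            self._schedule.setdefault(week, []).append((kind, ms_id, payload))

    def _journal(self, idx: int) -> Journal:
        return self.eco[idx]

    def _draw_reviewer(self, author: int) -> int:
        rid = int(self.rng.integers(self.pop.n))
        while rid == author:
            rid = int(self.rng.integers(self.pop.n))
        return rid

    def _make_reports(self, ms: Manuscript, j_idx: int, n: int, kind: str,
                      reviewers: Optional[List[int]] = None) -> list:
        journal = self._journal(j_idx)
        t = self.config.timing
        reports = []
        ids = reviewers if reviewers is not None else [self._draw_reviewer(ms.author_id) for _ in range(n)]
        for rid in ids:
            hours = conv.draw_review_hours(self.rng, t.review_hours_median, t.review_hours_log_sd)
            rep = conv.reviewer_assessment(ms.q_current, journal, self.config.errors,
                                           self.rng, manuscript_id=ms.id,
                                           reviewer_id=rid, kind=kind, hours=hours)
            reports.append(rep)
            self.log.reviews.append((self._week, ms.id, journal.id, rid, hours, kind))
            amount = apply_reviewer_reward(self.pop.view(rid), self.rng)
            if self.config.log_individual_events:
                self.log.rewards.append((self._week, rid, "review", amount))
        return reports, ids

    def _log_decision(self, ms: Manuscript, j_idx: int, kind: str, rnd: int) -> None:
        self.log.decisions.append((self._week, ms.id, self._journal(j_idx).id, kind, rnd))

    # ------------------------------------------------------------- transitions
    def _publish(self, ms: Manuscript, j_idx: int, decision_week: Optional[int] = None) -> None:
        journal = self._journal(j_idx)
        week = self._week
        ms.set_status("published")
        ms.terminal_week = week if decision_week is None else decision_week
        ms.published_journal = journal.id
        self.log.publications.append((week, ms.id, journal.id, ms.q_current))
        if self.variant == "crowdsourcing":
            amount = pol.release_remaining_si(ms, journal)
        else:
            amount = journal.reputation * ms.q_current
        self.log.si_ledger.append((week, ms.id, amount))
        reward = apply_publication_rewards(self.pop.view(ms.author_id), ms, self.rng)
        if self.config.log_individual_events:
            self.log.rewards.append((week, ms.author_id, "publication", reward))
        self.pop.busy[ms.author_id] = False

    def _abandon(self, ms: Manuscript) -> None:
        ms.set_status("discussion_unindexed" if ms.si_released > 0 else "abandoned")
        ms.terminal_week = self._week
        if ms.status == "discussion_unindexed":
            self.log.si_ledger.append((self._week, ms.id, pol.release_remaining_si(ms, None)))
        self.pop.busy[ms.author_id] = False

    def _consider_resubmission(self, ms: Manuscript, j_idx: int) -> None:
        sharing = self.variant in ("cascade", "portable")
        p = (pol.cascade_resubmission_probability(ms.n_submissions) if sharing
             else conv.resubmission_probability(ms.n_submissions))
        if self.rng.uniform() >= p:
            self._abandon(ms)
            return
        carry = False
        target: Optional[int] = None
        if sharing and ms.last_shared_review is not None:
            # the author accepts the editor's review-sharing proposal w.p. P_cas
            carry = self.rng.uniform() < self.policy.p_cascade_accept
        if self.variant == "cascade" and carry:
            target = pol.cascade_select_journal(self._journal(j_idx), self.eco, self.rng)
            if target is None:  # group-lowest journal: nowhere left to cascade
                self._abandon(ms)
                return
        else:
            target = conv.select_resubmission_journal(ms.q_initial, self.eco, self.rng)
        arrival = self._week + self.config.timing.resubmission_gap_weeks
        ms.n_submissions += 1
        via = "conventional"
        if carry:
            via = "cascade" if self.variant == "cascade" else "shared"
        ms.history.append(SubmissionRecord(self._journal(target).id, arrival, via))
        stage = "triage" if carry else "desk"
        self._at(arrival + self.config.timing.desk_weeks, stage, ms.id, {"j": target})

    # ----------------------------------------------------------------- events
    def _ev_desk(self, ms: Manuscript, payload: dict) -> None:
        j_idx = payload["j"]
        journal = self._journal(j_idx)
        q_e = float(conv.editor_assessment(ms.q_current, self.rng,
                                           self.config.errors.editor_halfwidth))
        outcome, n_rev = conv.desk_decision(q_e, journal, self.rng)
        self._log_decision(ms, j_idx, outcome.kind, 0)
        if outcome.kind == "desk_reject":
            self._consider_resubmission(ms, j_idx)
            return
        if self.variant == "crowdsourcing":
            si_attention = pol.initial_scientific_information(journal, ms.q_current)
            self._crowd_passers.append((ms, j_idx, si_attention))
        else:
            self._at(self._week + self.config.timing.review_weeks, "round1",
                     ms.id, {"j": j_idx, "n": n_rev})

    def _finalize_crowd_week(self) -> None:
        """Post the week's discussion papers and attract their commenters."""
        if not self._crowd_passers:
            return
        mean_si = float(np.mean([s for _, _, s in self._crowd_passers]))
        forced = self.policy.forced_comment_count
        for ms, j_idx, s in self._crowd_passers:
            if s > 0:  # each posting releases its initial information AR_j * Q
                ms.si_released += s
                self.log.si_ledger.append((self._week, ms.id, s))
            if forced is not None:
                n_online = forced
            elif mean_si > 0:
                n_online = pol.n_online_commenters(s, mean_si)
            else:
                n_online = 0
            n_inv = int(self.rng.integers(2, 4))
            self._at(self._week + self.config.timing.review_weeks, "crowd_round",
                     ms.id, {"j": j_idx, "n_inv": n_inv, "n_online": n_online})
        self._crowd_passers.clear()

    def _ev_round1(self, ms: Manuscript, payload: dict) -> None:
        j_idx, n_rev = payload["j"], payload["n"]
        journal = self._journal(j_idx)
        reports, reviewer_ids = self._make_reports(ms, j_idx, n_rev, "invited")
        decision = conv.first_round_decision(reports, journal, self.rng)
        ms.last_shared_review = decision.deciding_q
        self._log_decision(ms, j_idx, decision.kind, 1)
        if decision.kind == "accept":
            self._publish(ms, j_idx)
        elif decision.kind == "reject":
            self._consider_resubmission(ms, j_idx)
        else:  # major revision
            self._at(self._week + self.config.timing.revision_weeks, "revise_done",
                     ms.id, {"j": j_idx, "reviewers": reviewer_ids})

    def _ev_revise_done(self, ms: Manuscript, payload: dict) -> None:
        j_idx = payload["j"]
        r_imp = conv.revise_manuscript(ms, self.pop.view(ms.author_id), self.rng)
        if self.config.log_individual_events and r_imp:
            self.log.rewards.append((self._week, ms.author_id, "revision_investment", -r_imp))
        if self.variant == "rro":
            decision = pol.rro_final_decision(ms.q_current, self._journal(j_idx),
                                              self.rng, self.config.errors.editor_halfwidth)
            self._log_decision(ms, j_idx, decision.kind, 2)
            if decision.kind == "accept":
                self._publish(ms, j_idx)
            else:
                self._consider_resubmission(ms, j_idx)
            return
        self._at(self._week + self.config.timing.review_weeks, "round2",
                 ms.id, {"j": j_idx, "reviewers": payload["reviewers"]})

    def _ev_round2(self, ms: Manuscript, payload: dict) -> None:
        j_idx = payload["j"]
        # same reviewers re-evaluate the revised score with fresh error draws
        reports, _ = self._make_reports(ms, j_idx, len(payload["reviewers"]),
                                        "invited", reviewers=payload["reviewers"])
        decision = conv.second_round_decision(reports, self._journal(j_idx), self.rng)
        ms.last_shared_review = decision.deciding_q
        self._log_decision(ms, j_idx, decision.kind, 2)
        if decision.kind == "accept":
            self._publish(ms, j_idx)
        else:
            self._consider_resubmission(ms, j_idx)

    def _ev_triage(self, ms: Manuscript, payload: dict) -> None:
        j_idx = payload["j"]
        verdict, _q_e = pol.shared_review_triage(
            ms.last_shared_review, ms.q_current, self._journal(j_idx),
            self.policy.concordance_alpha, self.rng,
            self.config.errors.editor_halfwidth)
        if verdict == "immediate_accept":
            self._log_decision(ms, j_idx, "accept", 0)
            self._publish(ms, j_idx)
        elif verdict == "revise_then_editor":
            self._log_decision(ms, j_idx, "shared_review_revision", 0)
            self._at(self._week + self.config.timing.revision_weeks,
                     "triage_editor", ms.id, {"j": j_idx})
        else:  # fresh reviews: conventional handling from the review stage
            self._log_decision(ms, j_idx, "sent_to_review", 0)
            n_rev = int(self.rng.integers(2, 4))
            self._at(self._week + self.config.timing.review_weeks, "round1",
                     ms.id, {"j": j_idx, "n": n_rev})

    def _ev_triage_editor(self, ms: Manuscript, payload: dict) -> None:
        j_idx = payload["j"]
        journal = self._journal(j_idx)
        r_imp = conv.revise_manuscript(ms, self.pop.view(ms.author_id), self.rng)
        if self.config.log_individual_events and r_imp:
            self.log.rewards.append((self._week, ms.author_id, "revision_investment", -r_imp))
        q_e = float(conv.editor_assessment(ms.q_current, self.rng,
                                           self.config.errors.editor_halfwidth))
        kind = "accept" if q_e >= journal.t_max else "reject"
        self._log_decision(ms, j_idx, kind, 2)
        if kind == "accept":
            self._publish(ms, j_idx)
        else:
            self._consider_resubmission(ms, j_idx)

    def _ev_crowd_round(self, ms: Manuscript, payload: dict) -> None:
        j_idx = payload["j"]
        journal = self._journal(j_idx)
        invited, _ = self._make_reports(ms, j_idx, payload["n_inv"], "invited")
        online, _ = self._make_reports(ms, j_idx, payload["n_online"], "online")
        q_r = pol.crowd_decision(online, invited, payload["n_inv"],
                                 self.policy.crowd_aggregation, self.rng)
        if q_r >= journal.t_max:
            self._log_decision(ms, j_idx, "accept", 1)
            self._at(self._week + self.config.timing.revision_weeks, "index",
                     ms.id, {"j": j_idx, "decision_week": self._week})
        else:
            self._log_decision(ms, j_idx, "reject", 1)
            self._consider_resubmission(ms, j_idx)

    def _ev_index(self, ms: Manuscript, payload: dict) -> None:
        # accepted discussion papers are revised once, then indexed
        r_imp = conv.revise_manuscript(ms, self.pop.view(ms.author_id), self.rng)
        if self.config.log_individual_events and r_imp:
            self.log.rewards.append((self._week, ms.author_id, "revision_investment", -r_imp))
        self._publish(ms, payload["j"], decision_week=payload["decision_week"])

    _HANDLERS = {
        "desk": _ev_desk,
        "round1": _ev_round1,
        "revise_done": _ev_revise_done,
        "round2": _ev_round2,
        "triage": _ev_triage,
        "triage_editor": _ev_triage_editor,
        "crowd_round": _ev_crowd_round,
        "index": _ev_index,
    }

    # ------------------------------------------------------------------- loop
    def _submit_new(self) -> None:
        idle = self.pop.idle_indices()
        submitters = sample_weekly_submitters(idle, self.config.calibration, self.rng)
        for a in submitters:
            a = int(a)
            s_level = self.pop.scientific_level(a)  # S(t_s), before the investment
            view = self.pop.view(a)
            r_inv = invest_resources(view, self.rng)
            if r_inv <= 0:
                continue  # degenerate agent: nothing to invest this week
            e_q = expected_quality(r_inv, s_level)
            q = draw_q_score(e_q, self.rng)
            j_idx = conv.select_first_journal(q, self.eco, self.rng)
            ms = Manuscript(id=self._next_ms_id, author_id=a, q_initial=q,
                            q_current=q, e_q=e_q, r_inv=r_inv, n_submissions=1,
                            first_week=self._week)
            ms.history.append(SubmissionRecord(self._journal(j_idx).id, self._week, "first"))
            self._next_ms_id += 1
            self.log.manuscripts[ms.id] = ms
            self.pop.busy[a] = True
            if self.config.log_individual_events:
                self.log.rewards.append((self._week, a, "investment", -r_inv))
            self._at(self._week + self.config.timing.desk_weeks, "desk", ms.id, {"j": j_idx})

    def run(self) -> RunResult:
        for week in range(self.config.total_weeks):
            self._week = week
            dr, db = self.pop.weekly_growth(self.rng)
            if self.config.log_individual_events:
                for i in range(self.pop.n):
                    self.log.growth.append((week, i, float(dr[i]), float(db[i])))
            self._submit_new()
            # drain every event due this week; handlers may schedule same-week
            # follow-ups when stage durations are configured to zero
            while week in self._schedule or self._crowd_passers:
                for kind, ms_id, payload in self._schedule.pop(week, ()):
                    ms = self.log.manuscripts[ms_id]
                    self._HANDLERS[kind](self, ms, payload)
                if self.variant == "crowdsourcing":
                    self._finalize_crowd_week()
        outcome = compute_outcomes(self.log, self.config)
        return RunResult(outcome=outcome, log=self.log, seed_used=self.seed_used,
                         config_digest=self.config.digest())


# ---------------------------------------------------------------------------
# Replication, comparison, sweeps
# ---------------------------------------------------------------------------

def run_simulation(config: SimulationConfig, seed=None,
                   ar_table: Optional[Dict[int, float]] = None) -> RunResult:
    """One deterministic run.  Crowdsourcing/immediate variants first run a
    conventional system under the same seed (hence the identical synthetic
    ecosystem) to estimate the per-journal acceptance rates AR_j, unless an
    ``ar_table`` is supplied."""
    config.validate()
    seed = config.master_seed if seed is None else seed
    if _crowd_equivalent(config.policy).variant == "crowdsourcing" and ar_table is None:
        conv_cfg = replace(config, policy=replace(config.policy, variant="conventional"))
        cal_run = Simulation(conv_cfg, seed).run()
        ar_table = estimate_ar(cal_run.log, range(config.calibration.n_journals))
    result = Simulation(config, seed, ar_table=ar_table).run()
    result.ar_table = ar_table
    return result


def _run_seeds(config: SimulationConfig, n_runs: int):
    return np.random.SeedSequence(config.master_seed).spawn(n_runs)


def replicate(config: SimulationConfig, n_runs: Optional[int] = None,
              keep_logs: bool = False) -> pd.DataFrame:
    """Run ``n_runs`` independent replicates (counter-spawned seeds) and return
    one row of outcome measures per run."""
    n = config.n_runs if n_runs is None else n_runs
    if n < 1:
        raise ValueError("n_runs must be >= 1")
    rows, logs = [], []
    for i, ss in enumerate(_run_seeds(config, n)):
        res = run_simulation(config, ss)
        row = {"run": i, **res.outcome.as_dict()}
        rows.append(row)
        if keep_logs:
            logs.append(res.log)
    df = pd.DataFrame(rows).set_index("run")
    if keep_logs:
        df.attrs["logs"] = logs
    return df


def summarize(runs: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of each outcome over replicate runs."""
    return pd.DataFrame({"mean": runs.mean(), "sd": runs.std(ddof=1) if len(runs) > 1
                         else pd.Series(0.0, index=runs.columns)})


def compare(config: SimulationConfig, variants: Sequence[str],
            n_runs: Optional[int] = None, baseline: str = "conventional") -> pd.DataFrame:
    """Run several policy variants under common random numbers and summarise.

    Per run index the same spawned seed is used for every variant, so all
    variants see the same journal ecosystem, population and submission stream.
    The baseline (conventional) runs also provide the AR_j tables consumed by
    the crowdsourcing/immediate variants.  Returns a frame indexed by
    (variant, outcome) with mean, sd and relative difference to baseline.
    """
    n = config.n_runs if n_runs is None else n_runs
    seeds = _run_seeds(config, n)
    all_variants = list(dict.fromkeys([baseline, *variants]))
    per_variant: Dict[str, pd.DataFrame] = {}
    ar_tables: List[Dict[int, float]] = []

    base_cfg = replace(config, policy=replace(config.policy, variant=baseline))
    rows = []
    for ss in seeds:
        res = run_simulation(base_cfg, ss)
        ar_tables.append(estimate_ar(res.log, range(config.calibration.n_journals)))
        rows.append(res.outcome.as_dict())
    per_variant[baseline] = pd.DataFrame(rows)

    for variant in all_variants:
        if variant == baseline:
            continue
        cfg_v = replace(config, policy=replace(config.policy, variant=variant))
        needs_ar = _crowd_equivalent(cfg_v.policy).variant == "crowdsourcing"
        rows = []
        for i, ss in enumerate(seeds):
            res = run_simulation(cfg_v, ss, ar_table=ar_tables[i] if needs_ar else None)
            rows.append(res.outcome.as_dict())
        per_variant[variant] = pd.DataFrame(rows)

    base_mean = per_variant[baseline].mean()
    out = []
    for variant in all_variants:
        df = per_variant[variant]
        for col in df.columns:
            base = base_mean[col]
            rel = (df[col].mean() - base) / base if (base != 0 and np.isfinite(base)) else np.nan
            out.append({"variant": variant, "outcome": col, "mean": df[col].mean(),
                        "sd": df[col].std(ddof=1) if len(df) > 1 else 0.0,
                        "rel_diff_vs_baseline": rel})
    return pd.DataFrame(out).set_index(["variant", "outcome"])


def sweep(configs: Dict[str, SimulationConfig], n_runs: Optional[int] = None) -> pd.DataFrame:
    """Replicate each named configuration; one summary row per (name, outcome)."""
    if not configs:
        raise ValueError("sweep needs at least one configuration")
    frames = []
    for name, cfg in configs.items():
        runs = replicate(cfg, n_runs)
        summary = summarize(runs)
        summary.insert(0, "config", name)
        frames.append(summary.rename_axis("outcome").reset_index())
    return pd.concat(frames, ignore_index=True).set_index(["config", "outcome"])
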