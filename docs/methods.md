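# Methods

## Model overview

`pubsim` is a discrete-time (weekly) stochastic agent-based model of
scientific publication and peer review. Three entity classes interact:
researchers (authors and reviewers), journals, and manuscripts. Each week:

1. every researcher's resources *R* and base scientific level *S_b* grow by
   independent U[0.1, 1] draws (the passage of time brings means and
   experience);
2. a number of idle researchers — N(850, 85) at the reference population of
   25,000, scaled linearly with population size — submit a new manuscript,
   investing *R*<sub>inv</sub> ~ U[0.2 *R*, 0.7 *R*];
3. all editorial events that have come due are processed in scheduling order:
   desk screenings, review rounds, revisions, review-sharing triages and
   indexations, with rewards and scientific-information (SI) releases applied
   as they fire.

A manuscript's latent quality is drawn once per (re)draw event,
*Q* ~ N(*E_Q*, 0.1 *E_Q*), with

*E_Q* = 0.8 · 0.1 *R*<sub>inv</sub> / (0.1 *R*<sub>inv</sub> + 1)
      + 0.2 · 0.01 *S* / (0.01 *S* + 1),

a saturating function that weights invested resources four times as heavily
as author standing and never reaches 1. All assessments are noisy functions
of *Q*: editors draw *Q_e* ~ U[0.9 *Q*, 1.1 *Q*]; reviewer reports are
*Q_r* ~ N(*Q* − *c*, *r*·*Q*), *r* = *r_r* + *r_j* − 0.05 *Q* floored at 0,
where *r_r* is categorical (0.1 with mass 0.65, 0.05 with 0.12, 0.01 with
0.13, and 0 with the remaining 0.10 — the stated masses total 0.90 and the
remainder is completed at "no error", the least-assumption choice), *r_j*
rises linearly from 0 at the top-ranked journal to 0.15 at the bottom, and a
competitive down-shift *c* ~ U[0.01, 0.05] appears with probability falling
linearly from 0.66 (top) to 0.10 (bottom). Draws that must be positive
(quality scores, reports, targeting widths) are truncated at zero by
resampling.

Decision rules, all sharp thresholds: desk-reject iff *Q_e* < *T*<sub>min</sub>;
first round accept iff the uniformly picked report ≥ *T*<sub>max</sub>,
reject iff < *T*<sub>min</sub> (revision wins at equality), otherwise one
major revision (*R*<sub>imp</sub> ~ N(8/60, 1/60) · *R*, truncated at 0, added
to the cumulative investment before *E_Q* is recomputed and *Q* redrawn — the
author's level is measured before the deduction, so expected quality never
decreases on revision); the second round accepts only at
*Q_r* ≥ *T*<sub>max</sub>. Rejected authors resubmit with probability
0.88^(N_sub − 1) — note this is 1 at the first rejection — targeting the
symmetric window 0.22 *Q*₀ ± 0.5 ε on *T*<sub>min</sub> (ε = 2·N(*Q*/5,
*Q*/20), resampled positive; *Q*₀ the initial score). An empty targeting
window falls back to the journal with the nearest *T*<sub>min</sub>,
guaranteeing progress.

## Policy variants

* **Re-review opt-out**: the major-revision branch ends with an editor-only
  call, *Q_e* ~ U[0.9, 1.1]·*Q*<sub>revised</sub> against *T*<sub>max</sub>;
  no second external round exists.
* **Cascade**: journals are allocated to *N_g* = 4 publisher groups by a
  categorical distribution whose first three probabilities are N(0.25, 0.025)
  (for other *N_g*, N(1/*N_g*, 0.1/*N_g*) with the remainder on the last).
  On rejection the author accepts the editor's proposal with probability
  *P*<sub>cas</sub> (default 1.0) and the manuscript moves, with its last
  review *Q_r*, to one of the next five lower-reputation journals of the same
  group (none left → abandoned). The receiving editor accepts outright if
  *Q_r* ≥ *T*<sub>max</sub>; asks for a revision and decides alone when
  |*Q_e* − *Q_r*|/*Q_r* ≤ α (default 0.1); otherwise commissions fresh
  reviews, after which handling is conventional from the review stage (the
  editor has already engaged, so no second desk screening). Resubmission
  probability is relaxed to 0.88^((N_sub−1)/2). Manuscripts rejected at the
  desk carry no *Q_r* and re-enter the conventional pipeline at a
  conventionally targeted journal; an author who declines the proposal does
  the same. Only the most recent picked report travels.
* **Portable**: identical triage and resubmission decay, but journal choice is
  the conventional 0.22 *Q*₀ window and the review always travels.
* **Crowdsourcing**: every desk-passing submission is posted as a discussion
  paper, releasing SI<sub>init</sub> = AR<sub>j</sub> · *Q* immediately, and
  attracts round(SI_init / mean(SI_total)²) online commenters (half-up
  rounding; mean over that week's postings), who use the invited reviewers'
  error model. The single decision round uses
  *Q_r* = (*Q*<sub>online</sub> + n·*Q*<sub>invited</sub>)/(n + 1) with *n*
  invited reviewers (configurable alternatives: unweighted mean of all
  reports, or a uniform pick). Accepted papers are revised once and indexed,
  releasing IF<sub>j</sub>·*Q_F* − ΣSI<sub>init</sub> (signed; AR_j can
  exceed IF_j, in which case the remainder is negative — implemented
  literally). A discussion paper abandoned after rejection loses 80 % of its
  released SI, for a lifetime total of 0.2·SI<sub>init</sub>. AR_j — a
  journal's acceptance rate among externally reviewed papers — is estimated
  from a conventional-system run under the same seed (hence the identical
  ecosystem); journals never reviewed get the ecosystem mean.
* **Immediate publication**: the crowdsourcing pathway with the commenter
  count forced to zero; under a shared seed its event log is identical to
  zero-comment crowdsourcing by construction, and the test suite asserts it.

Each posting of a manuscript at a new journal releases that journal's
AR_j·*Q* (a fresh posting is a fresh release of visibility); the manuscript's
cumulative release is what the terminal events reconcile, so every
manuscript's lifetime SI total is exactly IF_j·*Q_F* (published),
0.2 × (released) (abandoned discussion paper) or 0 (never posted).

## Synthetic calibration

The journal ecosystem the model was originally fitted to is not publicly
available, so `generate_journals` builds a synthetic stand-in:

* reputations are log-normal (σ = 1.3) rescaled so the maximum is exactly 1 —
  a heavy-tailed spread of roughly two orders of magnitude, mimicking how
  journal impact factors distribute, and wide enough that both targeting
  windows (first submission near *Q*, resubmission near 0.22 *Q*) are
  populated and cascade hops descend meaningfully;
* desk thresholds are proportional, *T*<sub>min</sub> = 0.7 · reputation;
* acceptance thresholds are affine with a floor,
  *T*<sub>max</sub> = 0.6 + 0.2 · reputation.

The affine floor encodes an empirical regularity: post-review acceptance
standards vary far less across journal tiers than desk standards do, but
still fall with reputation. Both departures from a purely proportional rule
are load-bearing. Purely proportional thresholds make every journal inside
the resubmission window accept with probability ≈ 1, so no manuscript ever
ends unpublished and the published/unpublished separation is undefined. A
*flat* floor, conversely, makes *T*<sub>max</sub> identical across the lower
ecosystem, which structurally zeroes the cascade immediate-accept channel
(a rejection implies *Q_r* below every journal's acceptance bar) and starves
the editor-decides triage path. The floor level 0.6 places acceptance bars
at or just below the typical post-revision expected quality (≈ 0.68–0.72
under the default economy), the regime in which an editor-only decision on a
revised manuscript is at least as permissive as a reviewer re-review.

A genuine trade-off remains inside this calibration family and is worth
stating plainly: long reviewed resubmission chains (which make review-sharing
spectacularly cheap) require acceptance bars *above* typical revised quality,
while a permissive editor stage (which makes opt-out publish more and screen
less) requires bars *below* it — a U(±10 %) editor is strictly sharper than a
N(0, 0.1–0.2 *Q*) reviewer at the margin, so it screens harder whenever the
bar sits above typical revised quality. The default calibration favours the
second regime with moderate chain lengths. Consequences visible in the
comparison suite: review-sharing systems cut reviewer effort by roughly a
quarter (not the larger savings an ecosystem with longer reviewed chains
would show) and shorten decision time; opt-out saves effort but, in this
calibration, *sharpens* rather than degrades the published/unpublished
separation; the immediate-release systems raise weekly SI release
substantially while publishing somewhat fewer papers, and settle fates a few
weeks sooner than the conventional median rather than leaving it unchanged.

Researchers start with *R*(0) ~ U[1, 100] and *S_b*(0) = 0 (any positive
spread works; all outcome measures are comparative). Stage durations are
fixed stand-ins for unavailable survey distributions — desk 2 weeks, external
round 6, revision 4, resubmission gap 1 — and per-review hours are log-normal
with median 5 h and log-sd 0.5. All of these are configuration fields.

### What the generator does not emulate

No reviewer fatigue, reciprocity or strategic behaviour; no author
collaboration networks; no journal birth/death or capacity limits; quality is
one-dimensional; durations are deterministic stage lengths rather than
empirical distributions. Passing comparisons therefore demonstrate the
mechanics and internal consistency of the policy variants under a plausible
synthetic ecosystem — not forecasts for any real publishing system.

## Outcome measures

Computed from the event log alone (everything is recomputable offline):

* **Hellinger distance** between published and unpublished papers' final
  quality scores — histogram estimator on a common 100-bin grid spanning the
  joint range (bin count configurable; at ~10⁴ samples the estimator is
  within 0.01 of the closed-form Gaussian value at n = 10⁶, which the test
  suite checks);
* **relative Q improvement**: (mean final − mean initial)/mean initial over
  all terminally decided papers first submitted after burn-in;
* **reviewer effort**: total review hours per year over 8 h/day ×
  (365 − 104 − 25.3) working days = 1885.6 h per work-year;
* **dissemination**: publications per year (counted at indexation), median
  weeks from first submission to the terminal decision (acceptance, or the
  rejection after which no resubmission occurs), mean quality of published
  papers (configurable to all papers), and mean weekly signed SI release.

Flow measures (publications, SI, hours) count events in the post-burn-in
window; cohort measures (Hellinger, improvement, median time, mean Q)
condition on first submission after burn-in and a terminal status inside the
horizon, avoiding censoring bias. Manuscripts still in flight at the horizon
are excluded from cohort measures; their already-released discussion-paper SI
remains in the weekly ledger, which is the correct flow accounting.

## Determinism and numerics

One `numpy` Generator per run, seeded by (master seed, run index) through
`SeedSequence` spawning, drives every draw in a fixed event order; identical
(config, seed) pairs give byte-identical event logs. Crowdsourcing runs
derive AR_j from a conventional run under the same seed; `compare()` reuses
its baseline runs for this, and runs all variants under common random
numbers. Degenerate cases: agents with no resources skip submission;
revision with no resources is a no-op; zero-width histogram ranges give
Hellinger 0; empty targeting windows use the nearest-threshold fallback;
group-probability draws outside (0, 1) are resampled up to 100 times before
erroring. The commenter count rounds half-up, so `si/mean² = 0.5` attracts
one commenter.

## Known limitations

Absolute levels of every outcome depend on the synthetic calibration and the
duration stand-ins; only comparisons between variants under common random
numbers are meaningful. The resubmission-targeting rule (a window on
*T*<sub>min</sub> around 0.22 *Q*₀) combined with per-journal
*T*<sub>min</sub> < *T*<sub>max</sub> forces wide revision bands at
low-reputation journals, inflating second-round traffic there; no calibration
in this family avoids that while staying selective. The reviewer pool is
unconstrained (any researcher can be drawn any week), so reviewer scarcity
effects are out of scope.
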