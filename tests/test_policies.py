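"""The five policy variants: opt-out, cascade, portable, crowdsourcing, immediate."""

import collections

import numpy as np
import pytest

from pubsim import (JournalEcosystem, Manuscript, allocate_groups,
                    cascade_resubmission_probability, cascade_select_journal,
                    crowd_decision, initial_scientific_information,
                    n_online_commenters, release_remaining_si,
                    resubmission_probability, rro_final_decision,
                    shared_review_triage)
from pubsim.agents import ReviewReport
from tests.conftest import make_journal


def report(q_r, kind="invited"):
    return ReviewReport(manuscript_id=0, reviewer_id=0, q_r=q_r, error_sd=0.0,
                        competitive=False, shift=0.0, hours=5.0, kind=kind)


class TestRroFinalDecision:
    def test_support_bounds(self, rng):
        j_easy = make_journal(t_min=0.3, t_max=0.45)  # 0.9 * 0.5 >= 0.45
        assert all(rro_final_decision(0.5, j_easy, rng).kind == "accept"
                   for _ in range(200))
        j_hard = make_journal(t_min=0.5, t_max=0.56)  # 1.1 * 0.5 < 0.56
        assert all(rro_final_decision(0.5, j_hard, rng).kind == "reject"
                   for _ in range(200))

    def test_acceptance_probability_closed_form(self, rng):
        q_rev, t_max = 0.8, 0.85
        journal = make_journal(t_min=0.6, t_max=t_max)
        accepts = np.mean([rro_final_decision(q_rev, journal, rng).kind == "accept"
                           for _ in range(40_000)])
        assert accepts == pytest.approx((1.1 * q_rev - t_max) / (0.2 * q_rev), abs=0.01)


class TestGroupAllocation:
    def test_every_journal_assigned(self, rng):
        journals = [make_journal(jid=i, reputation=1 - i / 200, rank=i / 104)
                    for i in range(105)]
        groups = allocate_groups(journals, 4, rng)
        assert len(groups) == 105
        assert all(j.group_id in range(4) for j in journals)

    def test_expected_shares_quarter_each(self, rng):
        counts = collections.Counter()
        reps = 60
        for _ in range(reps):
            journals = [make_journal(jid=i, reputation=1 - i / 200) for i in range(105)]
            for g in allocate_groups(journals, 4, rng):
                counts[g] += 1
        shares = np.array([counts[g] for g in range(4)]) / (105 * reps)
        assert np.allclose(shares, 0.25, atol=0.02)

    def test_two_groups_both_populated(self, rng):
        journals = [make_journal(jid=i, reputation=1 - i / 200) for i in range(105)]
        groups = set(allocate_groups(journals, 2, rng))
        assert groups == {0, 1}

    def test_invalid_group_count(self, rng):
        with pytest.raises(ValueError):
            allocate_groups([make_journal()], 1, rng)


class TestCascadeSelection:
    def _ecosystem(self, reputations, group=0):
        journals = [make_journal(jid=i, reputation=rep, t_min=0.5 * rep,
                                 t_max=0.8 * rep, group=group, rank=i / max(len(reputations) - 1, 1))
                    for i, rep in enumerate(reputations)]
        eco = JournalEcosystem(journals)
        eco.rebuild_groups()
        return eco

    def test_group_lowest_abandons(self, rng):
        eco = self._ecosystem([0.9, 0.5, 0.2])
        assert cascade_select_journal(eco[2], eco, rng) is None

    def test_single_lower_always_selected(self, rng):
        eco = self._ecosystem([0.9, 0.5])
        assert all(cascade_select_journal(eco[0], eco, rng) == 1 for _ in range(30))

    def test_only_next_five_reachable_uniformly(self, rng):
        reps = [0.9] + [0.8 - 0.1 * k for k in range(7)]  # 7 journals below the top
        eco = self._ecosystem(reps)
        picks = collections.Counter(cascade_select_journal(eco[0], eco, rng)
                                    for _ in range(10_000))
        assert set(picks) == {1, 2, 3, 4, 5}  # never the 6th or 7th lower
        for idx in picks:
            assert picks[idx] / 10_000 == pytest.approx(0.2, abs=0.02)

    def test_respects_group_boundaries(self, rng):
        journals = [make_journal(jid=0, reputation=0.9, group=0),
                    make_journal(jid=1, reputation=0.7, group=1),
                    make_journal(jid=2, reputation=0.5, group=0)]
        eco = JournalEcosystem(journals)
        eco.rebuild_groups()
        top = next(j for j in eco if j.id == 0)
        target = {cascade_select_journal(top, eco, rng) for _ in range(30)}
        assert all(eco[t].id == 2 for t in target)


class TestSharedReviewTriage:
    def test_immediate_accept_at_boundary(self, rng, journal):
        verdict, q_e = shared_review_triage(journal.t_max, 0.6, journal, 0.1, rng)
        assert verdict == "immediate_accept" and q_e is None

    def test_alpha_zero_always_fresh(self, rng, journal):
        # equality of a continuous Q_e with Q_r has measure zero
        for _ in range(100):
            verdict, _ = shared_review_triage(0.6, 0.6, journal, 0.0, rng)
            assert verdict == "fresh_reviews"

    def test_alpha_one_never_fresh_when_ratio_bounded(self, rng, journal):
        # with q_e <= 1.1q <= 2 q_prev the discordance ratio cannot exceed 1
        q, q_prev = 0.6, 0.4
        assert 1.1 * q <= 2 * q_prev
        for _ in range(200):
            verdict, _ = shared_review_triage(q_prev, q, journal, 1.0, rng)
            assert verdict in ("revise_then_editor", "immediate_accept")

    def test_invalid_prior_review(self, rng, journal):
        with pytest.raises(ValueError):
            shared_review_triage(0.0, 0.5, journal, 0.1, rng)


class TestCascadeResubmission:
    def test_values(self):
        assert cascade_resubmission_probability(1) == 1.0
        assert cascade_resubmission_probability(3) == pytest.approx(0.88)

    def test_resubmits_more_than_conventional(self):
        for n in range(1, 12):
            assert (cascade_resubmission_probability(n)
                    >= resubmission_probability(n))

    def test_invalid(self):
        with pytest.raises(ValueError):
            cascade_resubmission_probability(0)


class TestScientificInformation:
    def test_initial_release(self):
        assert initial_scientific_information(make_journal(ar=0.5), 0.8) == pytest.approx(0.4)
        assert initial_scientific_information(make_journal(ar=0.0), 0.9) == 0.0

    def test_requires_calibrated_ar(self):
        with pytest.raises(ValueError):
            initial_scientific_information(make_journal(ar=None), 0.8)

    def test_commenter_counts(self):
        assert n_online_commenters(0.16, 0.4) == 1  # ratio exactly 1
        assert n_online_commenters(0.0, 0.4) == 0
        assert n_online_commenters(0.3, 0.4) == 2  # 1.875 rounds half-up
        with pytest.raises(ValueError):
            n_online_commenters(0.1, 0.0)

    def _terminal(self, status, si_released, q_final=0.8):
        ms = Manuscript(id=0, author_id=0, q_initial=0.7, q_current=q_final,
                        e_q=0.7, r_inv=1.0, si_released=si_released)
        ms.status = status
        return ms

    def test_abandoned_discussion_retains_fifth(self):
        ms = self._terminal("discussion_unindexed", si_released=1.0)
        event = release_remaining_si(ms, None)
        assert event == pytest.approx(-0.8)
        assert ms.si_released + event == pytest.approx(0.2)

    def test_accepted_releases_remainder(self):
        journal = make_journal(reputation=0.9)
        ms = self._terminal("published", si_released=0.4, q_final=0.8)
        assert release_remaining_si(ms, journal) == pytest.approx(0.32)
        ms2 = self._terminal("published", si_released=0.72, q_final=0.8)
        assert release_remaining_si(ms2, journal) == pytest.approx(0.0)


class TestCrowdDecision:
    def test_weighted_mean_formula(self, rng):
        q_r = crowd_decision([report(0.6, "online")], [report(0.9)], 2,
                             "weighted_mean", rng)
        assert q_r == pytest.approx((0.6 + 2 * 0.9) / 3)

    def test_no_online_comments_uses_invited(self, rng):
        q_r = crowd_decision([], [report(0.77)], 3, "weighted_mean", rng)
        assert q_r == pytest.approx(0.77)

    @pytest.mark.parametrize("agg", ["weighted_mean", "average_all", "random_pick"])
    def test_unanimous_scores_invariant(self, rng, agg):
        online = [report(0.65, "online")] * 3
        invited = [report(0.65)] * 2
        assert crowd_decision(online, invited, 2, agg, rng) == pytest.approx(0.65)

    def test_average_all(self, rng):
        q_r = crowd_decision([report(0.6, "online")], [report(0.9), report(0.8)],
                             2, "average_all", rng)
        assert q_r == pytest.approx(np.mean([0.6, 0.9, 0.8]))

    def test_requires_invited(self, rng):
        with pytest.raises(ValueError):
            crowd_decision([report(0.6, "online")], [], 2, "weighted_mean", rng)
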