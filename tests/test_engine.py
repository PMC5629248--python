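"""Engine: determinism, scheduling, policy state machines, replication, config, CLI."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import pubsim
from pubsim import SimulationConfig, compute_outcomes, load_config, run_simulation, save_config
from pubsim.cli import main as cli_main
from pubsim.engine import Simulation, compare, replicate, sweep


def small_config(variant="conventional", researchers=400, journals=30,
                 horizon=2, burn_in=1, **overrides):
    cfg = SimulationConfig.test_profile(variant)
    cfg = dataclasses.replace(
        cfg,
        calibration=dataclasses.replace(cfg.calibration, n_researchers=researchers,
                                        n_journals=journals),
        horizon_years=horizon, burn_in_years=burn_in, n_runs=2, **overrides)
    return cfg


@pytest.fixture(scope="module")
def small_runs():
    """One small run per variant, shared across the module's assertions."""
    out = {}
    for variant in ("conventional", "rro", "cascade", "portable", "crowdsourcing"):
        out[variant] = run_simulation(small_config(variant), seed=123)
    return out


class TestDeterminism:
    def test_same_seed_identical(self):
        cfg = small_config(researchers=200, horizon=1, burn_in=0)
        a = run_simulation(cfg, seed=7)
        b = run_simulation(cfg, seed=7)
        assert a.outcome == b.outcome
        assert a.log.digest() == b.log.digest()

    def test_different_seeds_differ(self):
        cfg = small_config(researchers=200, horizon=1, burn_in=0)
        a = run_simulation(cfg, seed=7)
        b = run_simulation(cfg, seed=8)
        assert a.log.digest() != b.log.digest()


class TestConfigSurface:
    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config("cascade")
        path = tmp_path / "run.yaml"
        save_config(cfg, path)
        again = load_config(path)
        assert again.digest() == cfg.digest()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig.from_dict({"horizon_years": 1, "burn_in_years": 1})
        with pytest.raises(ValueError):
            SimulationConfig.from_dict({"policy": {"variant": "nope"}})
        with pytest.raises(ValueError):
            SimulationConfig.from_dict({"unknown_key": 1})
        with pytest.raises(ValueError):
            SimulationConfig.from_dict({"policy": {"mystery": 2}})

    def test_crowdsourcing_requires_calibration(self):
        cfg = small_config("crowdsourcing")
        with pytest.raises(ValueError):
            Simulation(cfg, seed=1)  # no ar_table and journals uncalibrated


class TestEventLogRecomputability:
    def test_outcomes_recomputable_offline(self, small_runs):
        res = small_runs["conventional"]
        assert compute_outcomes(res.log, small_config()) == res.outcome

    def test_burn_in_excluded(self, small_runs):
        log = small_runs["conventional"].log
        burn_in = small_config().burn_in_weeks
        pubs_all = len(log.publications)
        annual, *_ = pubsim.dissemination_summary(log, burn_in, 104)
        assert annual * 1.0 <= pubs_all  # burn-in publications dropped

    def test_jsonl_export(self, small_runs, tmp_path):
        path = tmp_path / "events.jsonl"
        pubsim.write_jsonl(small_runs["conventional"].log, path)
        lines = path.read_text().splitlines()
        assert len(lines) > 100
        weeks = [json.loads(l).get("week", 1 << 30) for l in lines]
        body = [w for w in weeks if w != 1 << 30]
        assert body == sorted(body)


class TestStatusAndConservation:
    def test_terminal_statuses_and_history(self, small_runs):
        for variant, res in small_runs.items():
            for ms in res.log.manuscripts.values():
                assert ms.status in ("in_process", "published", "abandoned",
                                     "discussion_unindexed")
                assert len(ms.history) == ms.n_submissions >= 1
                if ms.status != "in_process":
                    assert ms.terminal_week is not None

    def test_si_conservation_conventional(self, small_runs):
        res = small_runs["conventional"]
        totals = res.log.manuscript_si_totals()
        journals = {j.id: j for j in Simulation(small_config(), seed=123).eco}
        for ms in res.log.manuscripts.values():
            if ms.status == "published":
                expected = journals[ms.published_journal].reputation * ms.q_current
                assert totals[ms.id] == pytest.approx(expected)
            elif ms.status != "in_process":
                assert totals.get(ms.id, 0.0) == 0.0

    def test_si_conservation_crowdsourcing(self, small_runs):
        res = small_runs["crowdsourcing"]
        totals = res.log.manuscript_si_totals()
        journals = {j.id: j for j in Simulation(small_config(), seed=123).eco}
        checked = 0
        for ms in res.log.manuscripts.values():
            if ms.status == "published":
                expected = journals[ms.published_journal].reputation * ms.q_current
                assert totals[ms.id] == pytest.approx(expected)
                checked += 1
            elif ms.status == "discussion_unindexed":
                assert totals[ms.id] == pytest.approx(0.2 * ms.si_released)
                checked += 1
            elif ms.status == "abandoned":
                assert totals.get(ms.id, 0.0) == 0.0
        assert checked > 50

    def test_rro_has_no_second_review_round(self, small_runs):
        res = small_runs["rro"]
        # a second review round would put two review batches inside one
        # submission episode: count distinct review weeks per episode
        episodes = {}
        hist = {m.id: [h.week for h in m.history] for m in res.log.manuscripts.values()}
        for week, ms_id, j, rid, hours, kind in res.log.reviews:
            starts = [w for w in hist[ms_id] if w <= week]
            episodes.setdefault((ms_id, len(starts)), set()).add(week)
        assert episodes and all(len(weeks) == 1 for weeks in episodes.values())

    def test_cascade_hops_strictly_descend_reputation(self, small_runs):
        res = small_runs["cascade"]
        journals = {j.id: j for j in Simulation(small_config("cascade"), seed=123).eco}
        n_hops = 0
        for ms in res.log.manuscripts.values():
            for prev, rec in zip(ms.history, ms.history[1:]):
                if rec.via == "cascade":
                    assert (journals[rec.journal_id].reputation
                            < journals[prev.journal_id].reputation)
                    n_hops += 1
        assert n_hops > 20

    def test_portable_ignores_groups(self, small_runs):
        res = small_runs["portable"]
        assert any(r.via == "shared" for m in res.log.manuscripts.values()
                   for r in m.history)
        eco = Simulation(small_config("portable"), seed=123).eco
        assert all(j.group_id is None for j in eco)


class TestZeroNoiseEngine:
    def test_published_quality_clears_acceptance_threshold(self):
        cfg = small_config(researchers=200, horizon=1, burn_in=0,
                           errors=pubsim.ErrorModelParams.zero_noise())
        res = run_simulation(cfg, seed=5)
        journals = {j.id: j for j in Simulation(cfg, seed=5).eco}
        assert len(res.log.publications) > 20
        for week, ms_id, j_id, q_final in res.log.publications:
            assert q_final >= journals[j_id].t_max - 1e-12


class TestReplication:
    def test_replicate_rows_and_determinism(self):
        cfg = small_config(researchers=200, horizon=1, burn_in=0)
        runs = replicate(cfg, n_runs=2)
        assert len(runs) == 2
        again = replicate(cfg, n_runs=2)
        pd.testing.assert_frame_equal(runs, again)

    def test_compare_baseline_relative_difference_zero(self):
        cfg = small_config(researchers=200, horizon=1, burn_in=0)
        table = compare(cfg, variants=["rro"], n_runs=2)
        base = table.xs("conventional", level="variant")["rel_diff_vs_baseline"]
        assert np.allclose(base.dropna(), 0.0)
        assert {"conventional", "rro"} == set(table.index.get_level_values(0))

    def test_sweep_shape_and_empty_error(self):
        cfg = small_config(researchers=200, horizon=1, burn_in=0)
        cfg2 = dataclasses.replace(
            cfg, policy=dataclasses.replace(cfg.policy, variant="rro"))
        table = sweep({"base": cfg, "rro": cfg2}, n_runs=1)
        assert set(table.index.get_level_values("config")) == {"base", "rro"}
        with pytest.raises(ValueError):
            sweep({})


def test_cli_simulate_and_compare(tmp_path):
    cfg = small_config(researchers=150, journals=20, horizon=1, burn_in=0)
    cfg_path = tmp_path / "cfg.yaml"
    save_config(dataclasses.replace(cfg, n_runs=1), cfg_path)
    runner = CliRunner()
    out_dir = tmp_path / "out"
    result = runner.invoke(cli_main, ["simulate", "--config", str(cfg_path),
                                      "--seed", "3", "--out", str(out_dir)])
    assert result.exit_code == 0, result.output
    assert (out_dir / "runs.csv").exists() and (out_dir / "summary.csv").exists()
    meta = json.loads((out_dir / "run_metadata.json").read_text())
    assert meta["master_seed"] == 3

    result = runner.invoke(cli_main, ["compare", "--config", str(cfg_path),
                                      "--seed", "3", "--variants", "rro",
                                      "--out", str(tmp_path / "cmp.csv")])
    assert result.exit_code == 0, result.output
    assert (tmp_path / "cmp.csv").exists()
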