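"""Study orchestration: trials, sweeps, rank consistency, toy experiment, CLI."""

import json

import numpy as np
import pandas as pd
import pytest

from msmselect.cli import cli_main
from msmselect.experiments import (HyperTrial, count_discordant_pairs,
                                   observation_ledger, rank_consistency,
                                   run_sweep, run_trial, spearman,
                                   toy_inversion_experiment)
from msmselect.lag_select import LagGrid
from msmselect.resampling import BootstrapPlan, BootstrapSummary
from msmselect.tpe_opt import table2_space


class TestSpearman:
    def test_identical_and_reversed(self):
        x = [3.0, 1.0, 4.0, 1.5]
        assert spearman(x, x) == 1.0
        assert spearman(x, [-v for v in x]) == -1.0

    def test_hand_computed_value(self):
        # d = (0, 1, -1, 0); rho = 1 - 6*2/(4*15) = 0.8
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_discordant_pair_counting(self):
        assert count_discordant_pairs([1, 2, 3], [1, 2, 3]) == 0
        assert count_discordant_pairs([1, 2, 3], [3, 2, 1]) == 3
        assert count_discordant_pairs([1, 2, 3, 4], [1, 3, 2, 4]) == 1


class TestLedger:
    def test_study_design_accounting(self):
        assert observation_ledger(n_trials=140, n_lags=10, n_boot=100) == 8_400_000

    def test_scaled_formula_verified_by_direct_count(self, toy_dtrajs):
        grid = LagGrid(lags=(1, 3, 5), threshold=0.1)
        plan = BootstrapPlan(subtrajectory_length=200, n_boot=3, seed=0)
        k_range = (2, 3)
        trials, ledger = run_sweep(table2_space(), 2, toy_dtrajs, grid, plan,
                                   seed=1, k_range=k_range, stratify_feature=False)
        # discrete data skips the feature stage; 2 trials x 3 lags x 6 observables
        direct_rows = sum(len(t.to_rows()) for t in trials)
        assert ledger["recorded_rows"] == direct_rows == 2 * 3 * 6
        assert ledger["recorded_observations"] == direct_rows * 3
        assert ledger["designed_observations"] == observation_ledger(2, 3, 3, 6)

    def test_single_trial_ledger_counts_rows(self, toy_dtrajs):
        grid = LagGrid(lags=(1, 2, 3), threshold=0.1)
        plan = BootstrapPlan(100, 2, seed=0)
        trials, ledger = run_sweep(table2_space(), 1, toy_dtrajs, grid, plan,
                                   seed=0, k_range=(2,), stratify_feature=False,
                                   csv_path=None)
        assert ledger["recorded_rows"] == len(trials[0].to_rows())


class TestRunTrial:
    GRID = LagGrid(lags=(1, 2, 4), threshold=0.1)
    PLAN = BootstrapPlan(subtrajectory_length=250, n_boot=50, seed=3)

    def test_ground_truth_t2_within_bootstrap_ci(self, toy_model, toy_dtrajs):
        """On perfectly discretized Markovian data the true timescale lies in
        the bootstrap interval at every lag."""
        trial = run_trial({}, toy_dtrajs, self.GRID, self.PLAN, k_range=(2, 3))
        lam2 = toy_model.eigenvalues()[1]
        # Markovian truth: t2 = -lag/ln(lambda2^lag) = -1/ln(lambda2), lag free
        true_t2 = -1.0 / np.log(lam2)
        for lag in self.GRID.lags:
            s = trial.observables[lag]["t_2"]
            assert s.ci_low <= true_t2 <= s.ci_high

    def test_white_noise_data_scores_near_one(self):
        rng = np.random.default_rng(0)
        dtrajs = [rng.integers(0, 5, size=1000) for _ in range(4)]
        trial = run_trial({}, dtrajs, self.GRID, self.PLAN, k_range=(2,))
        s = trial.observables[1]["vamp2eq_2"]
        assert s.median == pytest.approx(1.0, abs=0.01)

    def test_identical_theta_and_seed_identical_trial(self, toy_dtrajs):
        a = run_trial({}, toy_dtrajs, self.GRID, self.PLAN, k_range=(2,), seed=5)
        b = run_trial({}, toy_dtrajs, self.GRID, self.PLAN, k_range=(2,), seed=5)
        assert a.observables == b.observables

    def test_continuous_pipeline_runs_and_dihedrals_fail_gracefully(self, double_well_traj):
        _, traj = double_well_traj
        theta = {"feature": "distance", "tica_dim": 2, "tica_lag": 5, "n_clusters": 12}
        trial = run_trial(theta, [traj[:4000]], self.GRID,
                          BootstrapPlan(500, 4, seed=1), k_range=(2,), seed=2)
        assert trial.observables and not trial.failures
        # 1-D particle data cannot produce dihedral angles: recorded, not raised
        bad = run_trial({"feature": "dihedral", "tica_dim": 2, "tica_lag": 5,
                         "n_clusters": 12}, [traj[:4000]], self.GRID,
                        BootstrapPlan(500, 4, seed=1), k_range=(2,), seed=2)
        assert len(bad.failures) == len(self.GRID.lags)


def _synthetic_trials(scores_per_lag):
    """Build HyperTrial objects from a {lag: [score per trial]} table."""
    lags = list(scores_per_lag)
    n = len(scores_per_lag[lags[0]])
    trials = []
    for i in range(n):
        t = HyperTrial(trial_id=i, theta={})
        for lag in lags:
            v = scores_per_lag[lag][i]
            n_valid = 1 if np.isfinite(v) else 0
            t.observables[lag] = {"vamp2eq_2": BootstrapSummary(v, v, v, n_valid)}
        trials.append(t)
    return trials


class TestRankConsistency:
    def test_monotone_transforms_give_perfect_consistency(self):
        quality = np.array([0.1, 0.9, 0.4, 0.7, 0.2])
        table = {1: list(quality), 5: list(quality**2), 10: list(np.exp(quality))}
        cm = rank_consistency(_synthetic_trials(table), vary="lag",
                              lags=[1, 5, 10], fixed_k=2)
        assert np.allclose(cm.rho, 1.0)

    def test_independent_scores_near_zero_mean_offdiagonal(self):
        rng = np.random.default_rng(7)
        n = 120
        table = {lag: list(rng.standard_normal(n)) for lag in (1, 5, 10, 20)}
        cm = rank_consistency(_synthetic_trials(table), vary="lag",
                              lags=[1, 5, 10, 20], fixed_k=2)
        off = cm.rho[~np.eye(4, dtype=bool)]
        assert np.mean(np.abs(off)) < 3 / np.sqrt(n)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(8)
        table = {lag: list(rng.uniform(size=10)) for lag in (1, 2)}
        cm = rank_consistency(_synthetic_trials(table), vary="lag",
                              lags=[1, 2], fixed_k=2)
        assert np.allclose(np.diag(cm.rho), 1.0)
        assert np.allclose(cm.rho, cm.rho.T)

    def test_listwise_exclusion_of_incomplete_trials(self):
        table = {1: [0.1, 0.2, 0.3, 0.4], 2: [0.1, np.nan, 0.3, 0.4]}
        trials = _synthetic_trials(table)
        cm = rank_consistency(trials, vary="lag", lags=[1, 2], fixed_k=2)
        assert cm.rho[0, 1] == 1.0  # computed over the 3 complete trials

    def test_too_few_trials_rejected(self):
        table = {1: [0.1, 0.2], 2: [0.1, 0.2]}
        with pytest.raises(ValueError):
            rank_consistency(_synthetic_trials(table), vary="lag", lags=[1, 2], fixed_k=2)


class TestToyInversion:
    def test_report_structure_and_rank_equivalence(self):
        table, report = toy_inversion_experiment(n_replicates=300, traj_length=50,
                                                 lag=1, seed=3)
        assert {"t2", "vamp2_2", "vamp2eq_2"} <= set(table.columns)
        assert report["spearman_t2_vamp2eq"] == 1.0
        assert report["n_valid"] + report["n_failed"] == 300

    def test_replicate_floor_enforced(self):
        with pytest.raises(ValueError):
            toy_inversion_experiment(n_replicates=10)


class TestCLI:
    def test_unknown_subcommand_exits_2(self):
        assert cli_main(["frobnicate"]) == 2

    def test_toy_subcommand_writes_table_and_manifest(self, tmp_path, capsys):
        out = tmp_path / "toy"
        code = cli_main(["toy", "--replicates", "150", "--length", "30",
                         "--seed", "1", "--out", str(out)])
        assert code == 0
        assert (out / "toy_inversion.csv").exists()
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 1 and "config_hash" in manifest
        report = json.loads((out / "report.json").read_text())
        assert report["spearman_t2_vamp2eq"] == 1.0

    def test_simulate_and_sweep_resume(self, tmp_path):
        data_dir = tmp_path / "data"
        assert cli_main(["simulate", "--kind", "discrete", "--n-traj", "4",
                         "--length", "600", "--seed", "2", "--out", str(data_dir)]) == 0
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "data_dir: %s\nlags: [1, 2, 3]\nn_trials: 2\nn_boot: 3\n"
            "subtrajectory_length: 150\n" % data_dir
        )
        out = tmp_path / "sweep"
        assert cli_main(["sweep", "--config", str(cfg), "--seed", "3",
                         "--out", str(out)]) == 0
        n_rows = len(pd.read_csv(out / "sweep.csv"))
        assert n_rows > 0
        # re-running skips completed trials: no duplicate rows
        assert cli_main(["sweep", "--config", str(cfg), "--seed", "3",
                         "--out", str(out)]) == 0
        assert len(pd.read_csv(out / "sweep.csv")) == n_rows

    def test_lag_select_subcommand(self, tmp_path):
        rows = []
        for trial in range(2):
            for lag in (1, 2, 4, 8):
                rows.append({"trial_id": trial, "lag": lag, "observable": "t_2",
                             "median": 7.5, "ci_low": 7.0, "ci_high": 8.0, "n_valid": 5})
        csv = tmp_path / "sweep.csv"
        pd.DataFrame(rows).to_csv(csv, index=False)
        out = tmp_path / "lag.json"
        assert cli_main(["lag-select", "--sweep-csv", str(csv),
                         "--out", str(out)]) == 0
        assert json.loads(out.read_text())["selected_lag"] == 1
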