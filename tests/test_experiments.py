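"""Experiment runners, batch statistics, and the command-line interface."""

import json

import numpy as np
import pandas as pd
import pytest

from randkit import _batch as bt
from randkit import designs as dz
from randkit import experiments as ex
from randkit import inference as inf
from conftest import FISHER_TABLE_4V4


class TestBatchStatistics:
    def test_batch_t_test_matches_scalar_t_test(self, rng):
        delta, _ = dz.generate_sequences(dz.rand_rule(30), 30, 50, rng)
        y = rng.normal(0, 1, (50, 30)) + 0.8 * delta
        rej = bt.t_reject_batch(y, delta, 0.05)
        scalar = np.array(
            [inf.t_test_pooled(y[r], delta[r]).p_value < 0.05 for r in range(50)]
        )
        np.testing.assert_array_equal(rej, scalar)

    def test_batch_cox_matches_lifelines(self, rng):
        u = rng.normal(2.5, 0.8, 120)
        delta, _ = dz.generate_sequences(dz.bsd(3), 120, 4, rng)
        times = rng.exponential(1.0, (4, 120)) / np.exp(delta * np.log(0.6) + u)
        x = np.stack([delta.astype(float), np.broadcast_to(u, (4, 120))], axis=2)
        beta, se = bt.cox_wald_batch(times, x)
        for r in range(4):
            ref = inf.ph_test(times[r], None, delta[r], covariate_u=u, adjust=True)
            # both solvers iterate to ~1e-5 precision on the coefficient
            assert beta[r, 0] == pytest.approx(ref.extras["log_hr"], abs=1e-4)
            assert se[r, 0] == pytest.approx(ref.extras["se"], abs=1e-4)

    def test_martingale_residuals_sum_to_zero(self, rng):
        times = rng.exponential(1.0, (6, 80))
        resid = bt.martingale_residuals_batch(times, None)
        np.testing.assert_allclose(resid.sum(axis=1), 0.0, atol=1e-9)
        u = rng.normal(0, 1, 80)
        beta, _ = bt.cox_wald_batch(times, np.broadcast_to(u, (6, 80))[:, :, None].copy())
        resid_adj = bt.martingale_residuals_batch(times, u, beta[:, 0])
        np.testing.assert_allclose(resid_adj.sum(axis=1), 0.0, atol=1e-6)


class TestSmallTrialExperiment:
    def test_fisher_chart_reproduces_published_table(self):
        table, _ = ex.run_ex4_small_trial()
        assert len(table) == 25
        for _, row in table.iterrows():
            key = (row.successes_experimental, row.successes_control)
            assert round(row.fisher_p_1sided, 4) == pytest.approx(
                FISHER_TABLE_4V4[key], abs=5e-5
            )

    def test_exactly_three_outcomes_reach_the_evidence_threshold(self):
        table, _ = ex.run_ex4_small_trial()
        assert (table.decision == "S").sum() == 3

    def test_worked_example_pvalues_and_decisions(self):
        _, exact = ex.run_ex4_small_trial()
        got = dict(zip(exact.design, exact.exact_p_value.round(4)))
        assert got["Rand"] == 0.0714
        assert got["TBD"] == 0.0469
        assert got["PBD(2)"] == 0.1250
        assert got["PBD(4)"] == 0.0833
        assert got["population (Fisher)"] == 0.0714
        decisions = dict(zip(exact.design, exact.decision))
        assert decisions["PBD(2)"] == "F" and decisions["TBD"] == "S"


class TestRunners:
    def test_metrics_runner_is_reproducible_and_writes_outputs(self, tmp_path):
        designs = [dz.crd(), dz.pbd(2)]
        s1, _ = ex.run_ex1_metrics(designs, reps=300, master_seed=5, out_dir=tmp_path)
        s2, _ = ex.run_ex1_metrics(designs, reps=300, master_seed=5)
        pd.testing.assert_frame_equal(s1, s2)
        assert (tmp_path / "tradeoff_ranking.csv").exists()
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["master_seed"] == 5 and "runtime_seconds" in manifest

    def test_inference_runner_detects_power_against_null(self):
        df = ex.run_ex1_inference(
            designs=[dz.bsd(3)], models=("M1",), reps=300, L=300,
            target_powers=(0.9,), master_seed=2,
        )
        null = df[(df.scenario == "Null") & (df.test == "t_test")].rejection_rate.iloc[0]
        alt = df[(df.scenario == "Alt1") & (df.test == "t_test")].rejection_rate.iloc[0]
        assert null < 0.12
        assert alt > 0.75

    def test_bias_sweep_is_flat_for_crd_and_inflated_for_blocks(self):
        df = ex.run_bias_sweep(
            designs=[dz.crd(), dz.pbd(2)], nu_grid=(0.0, 0.8), reps=500, L=300,
            master_seed=3, tests=("t_test",),
        )
        crd_hi = df[(df.design == "CRD") & (df.nu == 0.8)].rejection_rate.iloc[0]
        pbd_hi = df[(df.design == "PBD(2)") & (df.nu == 0.8)].rejection_rate.iloc[0]
        assert crd_hi < 0.1
        assert pbd_hi > 0.4

    def test_survival_runner_smoke(self, tmp_path):
        df = ex.run_ex3_survival(
            designs=[dz.crd(), dz.pbd(2)], reps=200, L=200, master_seed=4,
            out_dir=tmp_path,
        )
        assert set(df.analysis) == {
            "pop_unadjusted", "pop_adjusted", "rand_unadjusted",
            "rand_adjusted", "baseline_imbalance",
        }
        assert df.rate.between(0, 1).all()
        power = df[(df.scenario == "Alternative") & (df.analysis == "pop_adjusted")]
        assert (power.rate > 0.8).all()
        assert (tmp_path / "survival_rates.csv").exists()

    def test_design_parsing_from_config_entries(self):
        spec = ex.parse_design({"name": "BSD", "mti": 3}, 50)
        assert spec.label == "BSD(3)"
        spec = ex.parse_design("CRD", 50)
        assert spec.name == "CRD"
        with pytest.raises(ValueError):
            ex.parse_design({"name": "XYZ"}, 50)


class TestCli:
    def test_smalltrial_command_writes_results(self, tmp_path):
        from click.testing import CliRunner

        from randkit.cli import main

        runner = CliRunner()
        result = runner.invoke(main, ["smalltrial", "--out", str(tmp_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "exact_randomization_pvalues.csv").exists()

    def test_metrics_command_with_yaml_config(self, tmp_path):
        from click.testing import CliRunner

        from randkit.cli import main

        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("reps: 100\ndesigns:\n  - CRD\n  - {name: PBD, block_size: 2}\n")
        out = tmp_path / "out"
        runner = CliRunner()
        result = runner.invoke(
            main, ["metrics", "--config", str(cfg), "--seed", "1", "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        ranking = pd.read_csv(out / "tradeoff_ranking.csv")
        assert set(ranking.design) == {"CRD", "PBD(2)"}
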