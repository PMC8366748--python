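"""Population-model and randomization-model tests."""

import numpy as np
import pytest

from randkit import designs as dz
from randkit import exact_engine as ee
from randkit import inference as inf
from conftest import FISHER_TABLE_4V4


class TestTTest:
    def test_equal_arms_give_zero_statistic(self):
        res = inf.t_test_pooled(np.array([1.0, 2, 3, 1, 2, 3]), np.array([1, 1, 1, 0, 0, 0]))
        assert res.statistic == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # E = {2, 4}, C = {1, 3}: pooled variance 2, SE sqrt(2), t = 1/sqrt(2)
        res = inf.t_test_pooled(np.array([2.0, 4, 1, 3]), np.array([1, 1, 0, 0]))
        assert res.statistic == pytest.approx(1 / np.sqrt(2))

    def test_identical_constant_arms(self):
        res = inf.t_test_pooled(np.array([5.0, 5, 5, 5]), np.array([1, 1, 0, 0]))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            inf.t_test_pooled(np.array([1.0, 2, 3]), np.array([1, 1, 1]))
        with pytest.raises(ValueError):
            inf.t_test_pooled(np.array([1.0, 1, 2, 2]), np.array([1, 1, 0, 0]))


class TestLinearRankStatistic:
    def test_hand_computed_example(self):
        s = inf.linear_rank_statistic(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1]))
        assert s == pytest.approx(2.0)

    def test_constant_responses_give_zero(self):
        assert inf.linear_rank_statistic(np.ones(6), np.array([1, 0, 1, 0, 1, 0])) == 0.0

    def test_label_swap_negates_for_balanced_sequences(self, rng):
        y = rng.normal(size=10)
        delta = np.array([1, 0] * 5)
        s = inf.linear_rank_statistic(y, delta)
        assert inf.linear_rank_statistic(y, 1 - delta) == pytest.approx(-s)


class TestFisherExact:
    def test_all_25_outcomes_match_published_values(self):
        for (se, sc), expected in FISHER_TABLE_4V4.items():
            p = inf.fisher_exact_1sided(se, 4, sc, 4).p_value
            assert round(p, 4) == pytest.approx(expected, abs=5e-5), (se, sc)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            inf.fisher_exact_1sided(5, 4, 0, 4)


class TestExactRandomization:
    @pytest.mark.parametrize(
        "spec, expected",
        [
            (dz.rand_rule(8), 0.0714),
            (dz.tbd(8), 0.0469),
            (dz.pbd(2), 0.1250),
            (dz.pbd(4), 0.0833),
        ],
    )
    def test_small_trial_worked_example(self, spec, expected, worked_example):
        delta, y = worked_example
        ref = ee.enumerate_reference_set(spec, 8)
        res = inf.exact_randomization_pvalue(ref, delta, y)
        assert round(res.p_value, 4) == pytest.approx(expected, abs=5e-5)

    def test_fisher_equivalence_under_random_allocation(self, worked_example):
        """For uniformly distributed balanced sequences the randomization test
        is a permutation test, so it must equal the one-sided Fisher p-value
        (spot check here; every binary outcome in the acceptance suite)."""
        delta, _ = worked_example
        ref = ee.enumerate_reference_set(dz.rand_rule(8), 8)
        for y in ([1, 1, 0, 0, 0, 0, 0, 1], [1, 0, 1, 0, 1, 0, 1, 0]):
            y = np.array(y, dtype=float)
            p_rand = inf.exact_randomization_pvalue(ref, delta, y).p_value
            se, sc = int(delta @ y), int((1 - delta) @ y)
            p_fisher = inf.fisher_exact_1sided(se, 4, sc, 4).p_value
            assert p_rand == pytest.approx(p_fisher, abs=1e-12)

    def test_sequence_outside_reference_set_raises(self, worked_example):
        _, y = worked_example
        ref = ee.enumerate_reference_set(dz.pbd(2), 8)
        with pytest.raises(ValueError):
            inf.exact_randomization_pvalue(ref, np.array([1, 1, 0, 0, 1, 0, 1, 0]), y)


class TestMonteCarloRandomization:
    def test_constant_responses_give_p_one(self, rng, worked_example):
        delta, _ = worked_example
        res = inf.mc_randomization_test(
            dz.rand_rule(8), delta, np.ones(8), "mean_diff", L=200, rng=rng
        )
        assert res.p_value == 1.0

    @pytest.mark.parametrize("statistic", ["mean_diff", "rank"])
    def test_converges_to_exact_enumeration(self, rng, worked_example, statistic):
        delta, y = worked_example
        y = y + rng.normal(0, 0.01, size=8)  # break ties, keep it generic
        ref = ee.enumerate_reference_set(dz.tbd(8), 8)
        exact_stat = "mean_diff" if statistic == "mean_diff" else "rank"
        p_exact = inf.exact_randomization_pvalue(
            ref, delta, y, statistic=exact_stat, direction="two"
        ).p_value
        L = 40_000
        res = inf.mc_randomization_test(dz.tbd(8), delta, y, statistic, L=L, rng=rng)
        se = np.sqrt(p_exact * (1 - p_exact) / L)
        assert abs(res.p_value - p_exact) < 4 * se + 1e-9

    def test_conservative_variant_never_smaller(self, rng, worked_example):
        delta, y = worked_example
        plain = inf.mc_randomization_test(
            dz.rand_rule(8), delta, y, L=500, rng=np.random.default_rng(0)
        )
        cons = inf.mc_randomization_test(
            dz.rand_rule(8), delta, y, L=500, rng=np.random.default_rng(0), conservative=True
        )
        assert cons.p_value >= plain.p_value


class TestProportionalHazards:
    def test_null_effect_recovered(self, rng):
        delta, _ = dz.generate_sequences(dz.pbd(4), 200, 1, rng)
        delta = delta[0]
        times = rng.exponential(1.0, 200)
        res = inf.ph_test(times, None, delta)
        assert abs(res.extras["log_hr"]) < 3 * res.extras["se"]
        assert res.p_value > 0.01

    def test_adjustment_absorbs_a_strong_covariate(self, rng):
        u = np.linspace(2, -2, 200)
        delta = np.tile([1, 0], 100).astype(np.int8)
        times = rng.exponential(1.0, 200) / np.exp(u)
        res = inf.ph_test(times, None, delta, covariate_u=u, adjust=True)
        assert abs(res.extras["log_hr"]) < 0.5


class TestPower:
    def test_published_design_power(self):
        # Delta/sigma = 0.95 at n = 50 gives ~91% power at two-sided 5%
        assert inf.power_ttest(50, 0.95) == pytest.approx(0.91, abs=0.005)

    def test_zero_effect_gives_alpha(self):
        assert inf.power_ttest(50, 0.0) == pytest.approx(0.05, abs=1e-6)

    def test_power_increases_with_sample_size(self):
        powers = [inf.power_ttest(n, 0.5) for n in (20, 50, 100)]
        assert powers == sorted(powers)

    def test_effect_for_power_inverts_power(self):
        eff = inf.effect_for_power(50, 0.8)
        assert inf.power_ttest(50, eff) == pytest.approx(0.8, abs=1e-6)
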