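"""Conditional assignment rules, sequence generation, and sequence probabilities."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from randkit import designs as dz
from conftest import twelve_designs


def state(assignments):
    return dz.AllocationState.from_assignments(assignments)


class TestAllocationProbability:
    @pytest.mark.parametrize(
        "spec, history, expected",
        [
            (dz.crd(), [1, 1, 1, 1], 0.5),
            (dz.bsd(3), [1, 1, 1], 0.0),  # D = 3: forced toward balance
            (dz.bsd(3), [0, 0, 0], 1.0),
            (dz.bcd(2 / 3), [1, 0], 0.5),  # balanced: fair coin
            (dz.bcd(2 / 3), [1], 1 / 3),  # E over-represented
            (dz.bcd(2 / 3), [0], 2 / 3),
            (dz.gbcd(2.0), [1, 0, 0], 0.8),  # N_C^2 / (N_E^2 + N_C^2) = 4/5
            (dz.gbcd(2.0), [], 0.5),
            (dz.rand_rule(8), [1, 1, 1], 0.2),  # (4 - 3) / (8 - 3)
            (dz.tbd(4), [1, 1], 0.0),  # E quota filled
            (dz.tbd(4), [0, 0], 1.0),
            (dz.pbd(2), [1], 0.0),  # block of 2 must close balanced
            (dz.pbd(4), [0, 0], 1.0),  # two C's in a half-filled block of 4
            (dz.bcdwit(2 / 3, 2), [1], 1 / 3),  # Efron zone
            (dz.bcdwit(2 / 3, 2), [1, 1], 0.0),  # MTI boundary: forced
            (dz.abcd(2.0), [1, 0, 1, 1], 1 / 5),  # D = 2: 1/(1 + 2^2)
            (dz.abcd(2.0), [0, 1, 0, 0], 4 / 5),
        ],
    )
    def test_rule_values(self, spec, history, expected):
        assert dz.allocation_probability(spec, state(history)) == pytest.approx(expected)

    def test_random_allocation_rule_matches_uniform_balanced_oracle(self):
        """The sequential RAND rule must equal the conditional frequency of E
        among uniformly drawn balanced sequences (brute-force enumeration)."""
        n = 8
        balanced = [
            s for s in itertools.product((0, 1), repeat=n) if sum(s) == n // 2
        ]
        assert len(balanced) == 70
        for prefix in ([1, 1, 1], [1, 0], [0, 0, 1, 0], []):
            matching = [s for s in balanced if list(s[: len(prefix)]) == prefix]
            oracle = sum(s[len(prefix)] for s in matching) / len(matching)
            got = dz.allocation_probability(dz.rand_rule(n), state(prefix))
            assert got == pytest.approx(oracle)

    def test_state_violations_raise(self):
        with pytest.raises(ValueError):
            dz.allocation_probability(dz.bsd(2), state([1, 1, 1]))
        with pytest.raises(ValueError):
            dz.allocation_probability(dz.rand_rule(4), state([1, 1, 1]))

    def test_missing_parameters_raise(self):
        with pytest.raises(ValueError):
            dz.DesignSpec("BSD")
        with pytest.raises(ValueError):
            dz.DesignSpec("BCD", coin_p=0.4)
        with pytest.raises(ValueError):
            dz.DesignSpec("PBD", block_size=3)
        with pytest.raises(ValueError):
            dz.DesignSpec("RAND", n=7)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    design_idx=st.integers(0, 11),
    steps=st.lists(st.booleans(), min_size=0, max_size=20),
)
def test_rule_is_symmetric_under_arm_relabeling(design_idx, steps):
    """phi(D) = 1 - phi(-D): swapping the arm labels mirrors the rule."""
    spec = twelve_designs(50)[design_idx]
    arr = np.array([int(b) for b in steps], dtype=np.int8)
    # walk the history, discarding prefixes that violate the design
    d = 0
    for i, a in enumerate(arr):
        phi = float(dz.conditional_prob_array(spec, i, d, 50))
        mirrored = float(dz.conditional_prob_array(spec, i, -d, 50))
        assert phi == pytest.approx(1.0 - mirrored, abs=1e-12)
        if (a and phi == 0.0) or (not a and phi == 1.0):
            return  # this branch of history is infeasible under the design
        d += 1 if a else -1


class TestGenerateSequence:
    def test_counts_and_imbalance_are_consistent(self, rng):
        for spec in twelve_designs(50):
            seq = dz.generate_sequence(spec, 50, rng)
            assert seq.n_e + seq.n_c == 50
            assert seq.imbalance_path[-1] == seq.n_e - seq.n_c
            assert np.all((seq.conditional_probs >= 0) & (seq.conditional_probs <= 1))

    def test_block_design_closes_every_block(self, rng):
        seqs, _ = dz.generate_sequences(dz.pbd(2), 6, 500, rng)
        d = np.cumsum(2 * seqs.astype(int) - 1, axis=1)
        assert np.all(d[:, 1::2] == 0)

    def test_mti_bound_never_exceeded(self, rng):
        seqs, _ = dz.generate_sequences(dz.bsd(3), 50, 2000, rng)
        d = np.cumsum(2 * seqs.astype(int) - 1, axis=1)
        assert np.abs(d).max() <= 3

    def test_quota_designs_end_balanced(self, rng):
        for spec in (dz.tbd(8), dz.rand_rule(8), dz.pbd(4)):
            seqs, _ = dz.generate_sequences(spec, 8, 300, rng)
            assert np.all(seqs.sum(axis=1) == 4)

    def test_crd_probabilities_are_half(self, rng):
        seq = dz.generate_sequence(dz.crd(), 20, rng)
        assert np.all(seq.conditional_probs == 0.5)

    def test_arm_relabeling_leaves_abs_imbalance_distribution_unchanged(self, rng):
        """Empirical check of the E<->C symmetry: mean signed imbalance ~ 0."""
        seqs, _ = dz.generate_sequences(dz.bcd(2 / 3), 50, 4000, rng)
        d_final = np.cumsum(2 * seqs.astype(int) - 1, axis=1)[:, -1]
        se = d_final.std() / np.sqrt(d_final.size)
        assert abs(d_final.mean()) < 4 * se + 1e-9


class TestSequenceProbability:
    def test_balanced_sequences_equiprobable_under_rand(self):
        spec = dz.rand_rule(8)
        assert dz.sequence_probability(spec, [1, 1, 0, 0, 1, 0, 1, 0]) == pytest.approx(1 / 70)
        assert dz.sequence_probability(spec, [1, 0, 1, 0, 1, 0, 1, 0]) == pytest.approx(1 / 70)

    def test_block2_sequences_equiprobable(self):
        assert dz.sequence_probability(dz.pbd(2), [1, 0, 0, 1, 1, 0, 0, 1]) == pytest.approx(1 / 16)

    def test_truncated_binomial_forced_tail(self):
        # two fair coin flips, then both remaining assignments are forced
        assert dz.sequence_probability(dz.tbd(4), [1, 1, 0, 0]) == pytest.approx(0.25)

    def test_infeasible_sequences_have_zero_probability(self):
        assert dz.sequence_probability(dz.bsd(2), [1, 1, 1, 0]) == 0.0
        assert dz.sequence_probability(dz.pbd(2), [1, 1, 0, 0]) == 0.0
        assert dz.sequence_probability(dz.rand_rule(4), [1, 1, 1, 0]) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            dz.sequence_probability(dz.rand_rule(8), [1, 0, 1, 0])

    def test_sequence_string_round_trip(self):
        seq = dz.AllocationSequence.from_string(dz.tbd(8), "CEECECCE")
        assert seq.to_string() == "CEECECCE"
        assert seq.n_e == 4
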