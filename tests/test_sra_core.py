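"""The SRA transform, NSAF, and internal-standard adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sccomp import (AbundanceProfile, adjusted_sra, nsaf, profile_from_matrix,
                    sra, sra_between_datasets, CountMatrix)

positive = st.floats(min_value=1e-3, max_value=1e6,
                     allow_nan=False, allow_infinity=False)


def make_profile(label, ids, counts, lengths=None):
    counts = np.asarray(counts)
    return AbundanceProfile(label, list(ids), counts, nsaf(counts, lengths))


class TestSRA:
    def test_half_fold_examples(self):
        up = sra(1.5, 1.0)
        assert up.value == pytest.approx(0.5)
        assert up.fold_text == "1.50-fold increase"
        down = sra(1.0, 1.5)
        assert down.value == pytest.approx(-0.5)
        assert down.fold_text == "1.50-fold decrease"

    def test_opposite_twofold_changes_average_to_zero(self):
        # ratios 2.0 and 0.5 would naively average to 1.25; on the SRA
        # scale they are +1 and -1 and cancel exactly
        up, down = sra(2.0, 1.0), sra(1.0, 2.0)
        assert (up.value, down.value) == (1.0, -1.0)
        assert up.value + down.value == 0.0
        assert np.mean([2.0, 0.5]) == pytest.approx(1.25)  # the broken naive mean

    @given(c=positive)
    @settings(derandomize=True, max_examples=100)
    def test_no_change_maps_to_zero(self, c):
        assert sra(c, c).value == 0.0

    @given(a=positive, b=positive)
    @settings(derandomize=True, max_examples=300)
    def test_antisymmetry_and_fold_identity(self, a, b):
        fwd, rev = sra(a, b), sra(b, a)
        assert fwd.value == pytest.approx(-rev.value, rel=1e-12, abs=1e-12)
        assert fwd.fold_magnitude == abs(fwd.value) + 1.0

    @pytest.mark.parametrize("a, b", [(0.0, 1.0), (1.0, 0.0), (-1.0, 2.0)])
    def test_nonpositive_inputs_rejected(self, a, b):
        with pytest.raises(ValueError):
            sra(a, b)


class TestNSAF:
    def test_equal_counts_equal_lengths(self):
        assert nsaf([10, 10], [100, 100]).tolist() == [0.5, 0.5]

    def test_length_normalization(self):
        # (10/100)/(10/100 + 10/200) = 2/3
        got = nsaf([10, 10], [100, 200])
        assert got == pytest.approx([2 / 3, 1 / 3])

    def test_single_protein_is_one(self):
        assert nsaf([7]).tolist() == [1.0]

    def test_zero_counts_stay_zero_and_rest_sum_to_one(self):
        got = nsaf([5, 0, 15], [100, 100, 300])
        assert got[1] == 0.0
        assert got.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            nsaf([0, 0])


class TestSraBetweenDatasets:
    def test_identical_profiles_give_zero(self):
        p = make_profile("a", ["x", "y"], [10, 20])
        q = make_profile("b", ["x", "y"], [10, 20])
        for pid in ["x", "y"]:
            assert sra_between_datasets(p, q, pid, basis="nsaf").value == 0.0

    def test_spc_basis_ratio(self):
        p = make_profile("a", ["x", "y"], [40, 10])
        q = make_profile("b", ["x", "y"], [10, 40])
        assert sra_between_datasets(p, q, "x", basis="spc").value == pytest.approx(3.0)

    def test_zero_count_yields_undefined_marker(self):
        p = make_profile("a", ["x", "y"], [40, 0])
        q = make_profile("b", ["x", "y"], [10, 5])
        assert sra_between_datasets(p, q, "y") is None

    @pytest.mark.parametrize("seed", range(3))
    def test_nsaf_and_spc_basis_agree_at_equal_totals_and_lengths(self, seed):
        rng = np.random.default_rng(seed)
        counts_a = rng.integers(1, 50, size=20)
        # permute to force equal totals with different per-protein counts
        counts_b = rng.permutation(counts_a)
        lengths = np.full(20, 350)
        ids = [f"p{i}" for i in range(20)]
        p = make_profile("a", ids, counts_a, lengths)
        q = make_profile("b", ids, counts_b, lengths)
        for pid in ids:
            v_nsaf = sra_between_datasets(p, q, pid, basis="nsaf").value
            v_spc = sra_between_datasets(p, q, pid, basis="spc").value
            assert v_nsaf == pytest.approx(v_spc, abs=1e-12)


class TestAdjustedSRA:
    def test_hand_computed_example(self):
        # A: k=30, IN1=10, IN2=15;  B: k=10, IN1=10, IN2=15
        # per-standard ratios: (30/10)/(10/10)=3, (30/15)/(10/15)=3 -> SRA +2
        a = make_profile("A", ["k", "IN1", "IN2"], [30, 10, 15])
        b = make_profile("B", ["k", "IN1", "IN2"], [10, 10, 15])
        res = adjusted_sra(a, b, "k", ["IN1", "IN2"])
        assert res.per_standard_sra == pytest.approx([2.0, 2.0])
        assert res.mean_sra == pytest.approx(2.0)
        assert res.n_standards == 2

    def test_matching_ratios_give_zero(self):
        # protein and every standard double together: each inner ratio is 1
        a = make_profile("A", ["k", "IN1", "IN2"], [20, 10, 30])
        b = make_profile("B", ["k", "IN1", "IN2"], [10, 5, 15])
        res = adjusted_sra(a, b, "k", ["IN1", "IN2"])
        assert res.mean_sra == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_nsaf_and_count_bases_agree(self, seed):
        # the sample-level NSAF normalizer and per-protein lengths cancel
        # in the ratio of ratios, so both bases give identical results
        rng = np.random.default_rng(seed)
        n = 30
        ids = [f"p{i}" for i in range(n)]
        lengths = rng.integers(100, 1000, size=n)
        a = make_profile("A", ids, rng.integers(1, 100, size=n), lengths)
        b = make_profile("B", ids, rng.integers(1, 100, size=n), lengths)
        standards = ids[1:6]
        via_counts = adjusted_sra(a, b, ids[0], standards, basis="spc")
        via_nsaf = adjusted_sra(a, b, ids[0], standards, basis="nsaf")
        assert via_counts.per_standard_sra == pytest.approx(
            via_nsaf.per_standard_sra, abs=1e-9)

    @pytest.mark.parametrize("scale", [2, 7])
    def test_scale_invariance_cancels_depth(self, scale):
        # multiplying every count of one profile by a constant (a pure
        # depth change) leaves each per-standard SRA unchanged
        rng = np.random.default_rng(42)
        n = 25
        ids = [f"p{i}" for i in range(n)]
        counts = rng.integers(1, 60, size=n)
        other = rng.integers(1, 60, size=n)
        a1 = make_profile("A", ids, counts)
        a2 = make_profile("A2", ids, counts * scale)
        b = make_profile("B", ids, other)
        r1 = adjusted_sra(a1, b, ids[0], ids[1:8])
        r2 = adjusted_sra(a2, b, ids[0], ids[1:8])
        assert r1.per_standard_sra == pytest.approx(r2.per_standard_sra, abs=1e-9)

    def test_zero_count_standards_dropped_with_reduced_n(self, caplog):
        a = make_profile("A", ["k", "IN1", "IN2"], [30, 10, 0])
        b = make_profile("B", ["k", "IN1", "IN2"], [10, 10, 5])
        with caplog.at_level("WARNING"):
            res = adjusted_sra(a, b, "k", ["IN1", "IN2"])
        assert res.n_standards == 1 and res.dropped_standards == ["IN2"]
        assert any("dropped" in r.message for r in caplog.records)

    def test_no_usable_standards_rejected(self):
        a = make_profile("A", ["k", "IN1"], [30, 0])
        b = make_profile("B", ["k", "IN1"], [10, 5])
        with pytest.raises(ValueError, match="no usable"):
            adjusted_sra(a, b, "k", ["IN1"])

    def test_undetected_protein_rejected(self):
        a = make_profile("A", ["k", "IN1"], [0, 5])
        b = make_profile("B", ["k", "IN1"], [10, 5])
        with pytest.raises(ValueError, match="undefined"):
            adjusted_sra(a, b, "k", ["IN1"])


def test_profile_from_matrix_uses_lengths():
    m = CountMatrix(["x", "y"], [("S", "A")], np.array([[10], [10]]),
                    lengths=np.array([100, 200]))
    prof = profile_from_matrix(m, "S:A")
    assert prof.nsaf == pytest.approx([2 / 3, 1 / 3])
    assert prof.spc.tolist() == [10, 10]
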