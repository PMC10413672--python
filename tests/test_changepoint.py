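import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tailseg import changepoint as cp


def random_profile(rng, n_bins, d=2, items_per_bin=3):
    n = n_bins * items_per_bin
    feats = rng.normal(size=(n, d))
    return cp.bin_by_rank(feats, rng.permutation(n), n_bins=n_bins)


class TestBinByRank:
    def test_one_item_per_bin(self):
        prof = cp.bin_by_rank(np.arange(30.0), np.arange(30), n_bins=30)
        assert np.all(prof.counts == 1)

    def test_remainder_goes_to_first_bins(self):
        prof = cp.bin_by_rank(np.arange(10.0), np.arange(10), n_bins=3)
        assert list(prof.counts) == [4, 3, 3]

    def test_sufficient_stats_match_brute_force_grouping(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(20, 2))
        ranks = rng.permutation(20)
        prof = cp.bin_by_rank(feats, ranks, n_bins=6)
        ordered = feats[np.argsort(ranks)]
        sizes = [4, 4, 3, 3, 3, 3]
        start = 0
        for b, size in enumerate(sizes):
            chunk = ordered[start : start + size]
            start += size
            assert prof.counts[b] == size
            assert np.allclose(prof.sums[b], chunk.sum(0))
            assert prof.sumsqs[b] == pytest.approx((chunk**2).sum())

    def test_input_validation(self):
        with pytest.raises(ValueError, match="n_bins"):
            cp.bin_by_rank(np.arange(5.0), np.arange(5), n_bins=6)
        with pytest.raises(ValueError, match="permutation"):
            cp.bin_by_rank(np.arange(5.0), np.array([0, 0, 1, 2, 3]), n_bins=2)
        with pytest.raises(ValueError, match="NaN"):
            cp.bin_by_rank(np.array([1.0, np.nan]), np.arange(2), n_bins=2)

    def test_within_bin_permutation_leaves_segmentation_unchanged(self):
        rng = np.random.default_rng(5)
        feats = rng.normal(size=(24, 2))
        ranks = np.arange(24)
        prof1 = cp.bin_by_rank(feats, ranks, n_bins=8)
        # swap two items inside bin 0 (ranks 0 and 2)
        ranks2 = ranks.copy()
        ranks2[[0, 2]] = ranks2[[2, 0]]
        prof2 = cp.bin_by_rank(feats, ranks2, n_bins=8)
        s1, s2 = cp.segment_dp(prof1, 2), cp.segment_dp(prof2, 2)
        assert list(s1.break_points) == list(s2.break_points)
        assert s1.total_error == pytest.approx(s2.total_error)


class TestSegmentDP:
    def test_k0_is_global_sse(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(30, 3))
        prof = cp.bin_by_rank(feats, np.arange(30), n_bins=10)
        seg = cp.segment_dp(prof, 0)
        sse = ((feats - feats.mean(0)) ** 2).sum()
        assert seg.total_error == pytest.approx(sse)
        assert seg.K == 0 and np.allclose(seg.segment_means[0], feats.mean(0))

    def test_two_constant_halves_break_at_midpoint(self):
        feats = np.r_[np.zeros(15), np.ones(15)]
        prof = cp.bin_by_rank(feats, np.arange(30), n_bins=10)
        seg = cp.segment_dp(prof, 1)
        assert list(seg.break_points) == [4]
        assert seg.total_error == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n_bins = int(rng.integers(4, 13))
            K = int(rng.integers(0, min(4, n_bins)))
            prof = random_profile(rng, n_bins, d=int(rng.integers(1, 4)))
            a = cp.segment_dp(prof, K)
            b = cp.brute_force_segment(prof, K)
            assert list(a.break_points) == list(b.break_points)
            assert a.total_error == pytest.approx(b.total_error, rel=1e-9)

    def test_error_non_increasing_in_k(self):
        rng = np.random.default_rng(9)
        prof = random_profile(rng, 12)
        errs = [cp.segment_dp(prof, k).total_error for k in range(8)]
        assert np.all(np.diff(errs) <= 1e-9)

    def test_planted_shifts_recovered_exactly_with_zero_noise(self):
        means = np.array([0.0, 4.0, -2.0])
        feats = np.repeat(means, 20)
        prof = cp.bin_by_rank(feats, np.arange(60), n_bins=12)
        seg = cp.segment_dp(prof, 2)
        assert list(seg.break_points) == [3, 7]  # bins of 5 items; shifts at 20, 40
        assert seg.total_error == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(seg.segment_means[:, 0], means)

    def test_segment_of_bin_partition(self):
        seg = cp.Segmentation(
            break_points=np.array([2, 6]),
            segment_means=np.zeros((3, 1)),
            total_error=0.0,
            n_bins=10,
        )
        assert list(seg.segment_of_bin()) == [0, 0, 0, 1, 1, 1, 1, 2, 2, 2]

    def test_guards(self):
        prof = random_profile(np.random.default_rng(0), 6)
        with pytest.raises(ValueError):
            cp.segment_dp(prof, 6)
        with pytest.raises(ValueError, match="cap"):
            cp.brute_force_segment(random_profile(np.random.default_rng(0), 31), 10, cap=1000)


class TestElbow:
    def test_hand_computed_curves(self):
        assert cp.select_k_elbow([100.0, 10.0, 9.0, 8.0, 7.0]) == 1
        assert cp.select_k_elbow([100.0, 60.0, 20.0, 19.5, 19.0, 18.5]) == 2

    def test_linear_curve_ties_to_zero(self):
        assert cp.select_k_elbow(np.linspace(100.0, 0.0, 8)) == 0

    def test_flat_curve_means_no_structure(self):
        # <5% total reduction: no segmentation signal
        assert cp.select_k_elbow([100.0, 99.0, 98.5, 98.0, 97.5]) == 0

    def test_increasing_curve_rejected(self):
        with pytest.raises(ValueError, match="increases"):
            cp.select_k_elbow([100.0, 50.0, 60.0, 40.0])

    def test_structureless_profile_selects_zero(self):
        # rank uncorrelated with features: binned means are flat
        rng = np.random.default_rng(11)
        feats = rng.normal(size=(900, 1))
        prof = cp.bin_by_rank(feats, rng.permutation(900), n_bins=30)
        assert cp.select_k_elbow(cp.error_curve(prof, 8)) == 0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    n_bins=st.integers(4, 10),
    k=st.integers(0, 3),
)
def test_dp_optimality_property(seed, n_bins, k):
    """DP equals exhaustive search and never worsens with an extra break."""
    rng = np.random.default_rng(seed)
    k = min(k, n_bins - 1)
    prof = random_profile(rng, n_bins)
    a = cp.segment_dp(prof, k)
    b = cp.brute_force_segment(prof, k)
    assert a.total_error == pytest.approx(b.total_error, rel=1e-9)
    if k + 1 < n_bins:
        assert cp.segment_dp(prof, k + 1).total_error <= a.total_error + 1e-9
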