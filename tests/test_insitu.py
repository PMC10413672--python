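import numpy as np
import pytest

from tailseg import insitu


class TestFindBounds:
    def test_linear_ramp_rule_derived_indices(self):
        ramp = np.linspace(0.0, 1.0, 101)  # value i/100 at index i
        b = insitu.find_bounds(ramp)
        assert b.pz_psm_boundary == 21  # first value > 0.20
        assert b.anterior_end == 100  # last value > 0.85

    def test_scale_invariance(self):
        ramp = np.linspace(0.0, 1.0, 101)
        b1 = insitu.find_bounds(ramp)
        b2 = insitu.find_bounds(1000.0 * ramp)
        assert (b1.pz_psm_boundary, b1.anterior_end) == (
            b2.pz_psm_boundary, b2.anterior_end,
        )

    def test_constant_profile_spans_everything(self):
        b = insitu.find_bounds(np.full(50, 3.0))
        assert b.pz_psm_boundary == 0 and b.anterior_end == 49

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            insitu.find_bounds(np.zeros(10))

    def test_bounds_ordering_invariant_on_random_profiles(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            prof = rng.uniform(0.01, 1.0, size=rng.integers(3, 60))
            b = insitu.find_bounds(prof)
            assert 0 <= b.pz_psm_boundary <= b.anterior_end < len(prof)

    def test_raising_low_threshold_never_moves_boundary_posterior(self):
        rng = np.random.default_rng(0)
        prof = np.clip(np.cumsum(rng.uniform(0, 1, 80)), 0, None)
        b_low = insitu.find_bounds(prof, low=0.2, high=0.95)
        b_high = insitu.find_bounds(prof, low=0.4, high=0.95)
        assert b_high.pz_psm_boundary >= b_low.pz_psm_boundary


class TestScaledPzLength:
    def test_ramp_arithmetic(self):
        assert insitu.scaled_pz_length(insitu.RegionBounds(21, 100, 101)) == 0.21

    @pytest.mark.parametrize("b, a, expected", [(0, 50, 0.0), (50, 50, 1.0)])
    def test_extremes(self, b, a, expected):
        assert insitu.scaled_pz_length(insitu.RegionBounds(b, a, 51)) == expected

    def test_anterior_at_tail_tip_rejected(self):
        with pytest.raises(ValueError):
            insitu.scaled_pz_length(insitu.RegionBounds(0, 0, 5))


class TestOtsu:
    def test_two_value_image_separated_exactly(self):
        rng = np.random.default_rng(1)
        img = np.where(rng.uniform(size=(30, 30)) < 0.4, 100.0, 0.0)
        mask = insitu.otsu_mask(img)
        assert np.array_equal(mask, img == 100.0)

    def test_bimodal_threshold_between_modes(self):
        rng = np.random.default_rng(2)
        img = np.r_[rng.normal(10, 1, 500), rng.normal(50, 1, 500)].reshape(20, 50)
        from skimage.filters import threshold_otsu

        t = threshold_otsu(img)
        assert 11 < t < 49  # strictly between the two modes
        mask = insitu.otsu_mask(img)
        assert np.array_equal(mask, img > 30)  # separates the populations

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            insitu.otsu_mask(np.ones((5, 5)))


class TestStraightAxisProfile:
    def test_uniform_image_flat_normalized_profile(self):
        img = np.full((10, 40), 7.0)
        profs = insitu.straight_axis_profile(img, np.ones_like(img, bool), 5)
        for side in ("left", "right"):
            assert np.allclose(profs[side], 1.0)

    def test_bright_column_peaks_there(self):
        img = np.zeros((10, 40))
        img[:, 25] = 10.0
        profs = insitu.straight_axis_profile(
            img, np.ones_like(img, bool), 5, sigma=0.0
        )
        assert int(np.nanargmax(profs["left"])) == 25

    def test_two_plateau_image_hand_means(self):
        # 6 rows x 4 cols; left = rows 0..2. Masked column means by hand.
        img = np.array(
            [
                [1.0, 2.0, 8.0, 8.0],
                [1.0, 2.0, 8.0, 8.0],
                [1.0, 2.0, 8.0, 8.0],
                [3.0, 3.0, 6.0, 6.0],
                [3.0, 3.0, 6.0, 6.0],
                [3.0, 3.0, 6.0, 6.0],
            ]
        )
        profs = insitu.straight_axis_profile(
            img, np.ones_like(img, bool), 3, sigma=0.0, normalize=False
        )
        assert np.allclose(profs["left"], [1.0, 2.0, 8.0, 8.0])
        assert np.allclose(profs["right"], [3.0, 3.0, 6.0, 6.0])

    def test_empty_side_mask_rejected(self):
        img = np.ones((4, 4))
        mask = np.zeros_like(img, bool)
        mask[2:] = True
        with pytest.raises(ValueError, match="left"):
            insitu.straight_axis_profile(img, mask, 2)


class TestCurvedAxis:
    def test_straight_perimeter_matches_straight_projection(self):
        rng = np.random.default_rng(3)
        img = np.tile(np.linspace(1.0, 5.0, 60), (8, 1)) + rng.normal(
            0, 0.01, (8, 60)
        )
        perimeter = np.column_stack([np.arange(60.0), np.full(60, -1.0)])
        prof, pos = insitu.curved_axis_profile(
            img, perimeter, window=6, normalize=False
        )
        cols = img.mean(axis=0)
        # compare interior (window-edge effects at the two ends)
        inner = slice(5, 55)
        expected = np.array([cols[max(0, int(p) - 3) : int(p) + 3].mean() for p in pos])
        assert np.allclose(prof[inner], expected[inner], atol=0.1)

    def test_quarter_circle_uniform_intensity_is_flat(self):
        n = 120
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx, yy)
        mask = (r > 60) & (r < 100) & (xx >= 0) & (yy >= 0)
        img = np.ones((n, n))
        theta = np.linspace(0.0, np.pi / 2, 200)
        perimeter = np.column_stack([110 * np.cos(theta), 110 * np.sin(theta)])
        prof, pos = insitu.curved_axis_profile(
            img, perimeter, mask=mask, window=12, normalize=False
        )
        interior = prof[~np.isnan(prof)][5:-5]
        assert np.allclose(interior, 1.0)

    def test_tie_projects_to_earlier_arc_position(self):
        # a point equidistant to both ends of a symmetric V-curve
        curve = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        s = insitu.project_to_axis(np.array([[1.0, 0.0]]), curve)
        assert s[0] == 0.0  # first vertex wins the tie

    def test_degenerate_perimeter_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            insitu.smooth_axis(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))


class TestScaledPzArea:
    def test_rectangle_straight_axis_ratio(self):
        # 100-px-long rectangular embryo, boundary at 30% of its length
        mask = np.ones((20, 100), dtype=bool)
        perimeter = np.column_stack([np.arange(100.0), np.full(100, -1.0)])
        ratio = insitu.scaled_pz_area(mask, perimeter, (30.0, 99.0))
        assert ratio == pytest.approx(0.3, abs=0.02)  # pixelization tolerance

    def test_empty_pz_region(self):
        mask = np.ones((5, 50), dtype=bool)
        perimeter = np.column_stack([np.arange(50.0), np.full(50, -1.0)])
        assert insitu.scaled_pz_area(mask, perimeter, (0.0, 49.0)) == 0.0

    def test_annular_sector_known_geometry(self):
        # quarter annulus r in [60, 100]; cut at 45 degrees: half the area
        n = 140
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx, yy)
        mask = (r > 60) & (r < 100)
        theta = np.linspace(0.0, np.pi / 2, 400)
        perimeter = np.column_stack([80 * np.cos(theta), 80 * np.sin(theta)])
        arc_total = 80 * np.pi / 2
        ratio = insitu.scaled_pz_area(
            mask, perimeter, (arc_total / 2, arc_total)
        )
        assert ratio == pytest.approx(0.5, abs=0.02)

    def test_no_pixels_in_region_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 0] = True
        perimeter = np.column_stack([np.arange(30.0), np.full(30, 20.0)])
        with pytest.raises(ValueError):
            insitu.scaled_pz_area(~mask & mask, perimeter, (1.0, 2.0))
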