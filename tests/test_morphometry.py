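"""Landmark morphometry: B:A ratio, log trend, ZLI angles, area, t tests."""

import numpy as np
import pytest
from scipy import stats as sps

from growthlines import synthetic
from growthlines.morphometry import (
    AnnotatedImage,
    LandmarkSet,
    area_positive,
    ba_ratio,
    despeckle,
    fit_log_trend,
    t_test,
    zli_angles,
)


def _rotate(points, theta, shift=(0.0, 0.0)):
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return np.asarray(points) @ rot.T + np.asarray(shift)


class TestBARatio:
    def _axis_aligned(self):
        return LandmarkSet(
            points={"X": [0.0, 0.0], "Y": [10.0, 0.0]},
            polylines={"optic_margin": [[4.0, -5.0], [4.0, 5.0]]},
        )

    def test_axis_aligned_construction(self):
        res = ba_ratio(self._axis_aligned())
        assert res.a_length == pytest.approx(10.0)
        assert res.b_length == pytest.approx(6.0)
        assert res.ratio == pytest.approx(0.6)

    def test_margin_through_y_gives_zero(self):
        lm = LandmarkSet(
            points={"X": [0.0, 0.0], "Y": [10.0, 0.0]},
            polylines={"optic_margin": [[10.0, -2.0], [10.0, 2.0]]},
        )
        assert ba_ratio(lm).ratio == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("theta", [0.3, np.pi / 6, 1.2])
    def test_rigid_rotation_invariance(self, theta):
        base = self._axis_aligned()
        rotated = LandmarkSet(
            points={k: _rotate(v, theta, (3.0, -7.0)) for k, v in base.points.items()},
            polylines={
                k: _rotate(v, theta, (3.0, -7.0)) for k, v in base.polylines.items()
            },
        )
        assert ba_ratio(rotated).ratio == pytest.approx(0.6, abs=1e-9)

    def test_margin_missing_a_segment_errors(self):
        lm = LandmarkSet(
            points={"X": [0.0, 0.0], "Y": [10.0, 0.0]},
            polylines={"optic_margin": [[15.0, -5.0], [15.0, 5.0]]},
        )
        with pytest.raises(ValueError, match="segment"):
            ba_ratio(lm)

    def test_coincident_landmarks_rejected(self):
        lm = LandmarkSet(
            points={"X": [1.0, 1.0], "Y": [1.0, 1.0]},
            polylines={"optic_margin": [[0.0, -1.0], [0.0, 1.0]]},
        )
        with pytest.raises(ValueError, match="coincide"):
            ba_ratio(lm)


class TestLogTrend:
    def test_noiseless_recovery(self):
        stages = np.array([10.0, 11, 14, 20])
        ratios = 2.0 * np.log(stages) + 1.0
        a, b = fit_log_trend(stages, ratios)
        assert a == pytest.approx(2.0, abs=1e-9)
        assert b == pytest.approx(1.0, abs=1e-9)

    def test_constant_ratios_give_zero_slope(self):
        a, b = fit_log_trend([10, 14, 20], [0.7, 0.7, 0.7])
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(0.7)

    def test_noisy_data_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        stages = np.array([8.0, 10, 12, 14, 17, 20])
        ratios = 0.4 * np.log(stages) + 0.2 + rng.normal(scale=0.05, size=6)
        a, b = fit_log_trend(stages, ratios)
        x = np.log(stages)
        design = np.stack([x, np.ones_like(x)], axis=1)
        oracle = np.linalg.solve(design.T @ design, design.T @ ratios)
        assert a == pytest.approx(oracle[0], abs=1e-12)
        assert b == pytest.approx(oracle[1], abs=1e-12)

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(8)
        stages = np.linspace(9, 21, 10)
        ratios = rng.random(10)
        a, b = fit_log_trend(stages, ratios)
        resid = ratios - (a * np.log(stages) + b)
        assert resid @ np.ones_like(stages) == pytest.approx(0.0, abs=1e-9)
        assert resid @ np.log(stages) == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_stage_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_log_trend([0, 10], [1, 2])


class TestZliAngles:
    def test_perpendicular_gives_90(self):
        lm = LandmarkSet(
            points={"base": [0.0, 0.0], "starA": [5.0, 0.0], "starP": [-3.0, 0.0]},
            polylines={"ZLI": [[0.0, 0.0], [0.0, 4.0]]},
        )
        res = zli_angles(lm)
        assert res.angle_a_deg == pytest.approx(90.0)
        assert res.angle_p_deg == pytest.approx(90.0)

    def test_parallel_gives_zero(self):
        lm = LandmarkSet(
            points={"base": [0.0, 0.0], "starA": [0.0, 7.0], "starP": [0.0, -7.0]},
            polylines={"ZLI": [[0.0, 0.0], [0.0, 4.0]]},
        )
        res = zli_angles(lm)
        assert res.angle_a_deg == pytest.approx(0.0, abs=1e-9)
        assert res.angle_p_deg == pytest.approx(180.0)

    def test_arbitrary_coordinates_match_arccos_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            zli = rng.normal(scale=5, size=(4, 2))
            base, a, p = rng.normal(scale=5, size=(3, 2))
            lm = LandmarkSet(
                points={"base": base, "starA": a, "starP": p}, polylines={"ZLI": zli}
            )
            d = zli[-1] - zli[0]
            for star, got in (
                (a, zli_angles(lm).angle_a_deg),
                (p, zli_angles(lm).angle_p_deg),
            ):
                v = star - base
                oracle = np.degrees(
                    np.arccos(np.clip(d @ v / (np.linalg.norm(d) * np.linalg.norm(v)), -1, 1))
                )
                assert got == pytest.approx(oracle, abs=1e-9)

    def test_reflection_keeps_angles_in_range(self):
        lm = LandmarkSet(
            points={"base": [0.0, 0.0], "starA": [3.0, 4.0], "starP": [-2.0, 1.0]},
            polylines={"ZLI": [[0.0, -1.0], [1.0, 5.0]]},
        )
        res = zli_angles(lm)
        reflected = LandmarkSet(
            points={k: v * np.array([-1.0, 1.0]) for k, v in lm.points.items()},
            polylines={k: v * np.array([-1.0, 1.0]) for k, v in lm.polylines.items()},
        )
        res_r = zli_angles(reflected)
        assert res_r.angle_a_deg == pytest.approx(res.angle_a_deg, abs=1e-9)
        assert res_r.angle_p_deg == pytest.approx(res.angle_p_deg, abs=1e-9)

    def test_zero_length_segment_errors(self):
        lm = LandmarkSet(
            points={"base": [0.0, 0.0], "starA": [0.0, 0.0], "starP": [1.0, 0.0]},
            polylines={"ZLI": [[0.0, 0.0], [0.0, 4.0]]},
        )
        with pytest.raises(ValueError, match="zero-length"):
            zli_angles(lm)


class TestAreaPositive:
    def test_all_zero_image_gives_zero(self):
        img = AnnotatedImage(
            image=np.zeros((32, 32), dtype=np.uint16),
            rois=[np.array([[2, 2], [2, 29], [29, 29], [29, 2]])],
        )
        assert area_positive(img, threshold=0).pixels == 0

    def test_clean_rectangle_counts_exactly(self):
        im = np.full((40, 40), 100, dtype=np.uint16)
        im[10:20, 5:25] = 1000  # 10 x 20 = 200 px
        img = AnnotatedImage(image=im, rois=[np.array([[0, 0], [0, 39], [39, 39], [39, 0]])])
        assert area_positive(img, threshold=500).pixels == 200

    def test_salt_removed_signal_intact(self):
        """Planted salt is despeckled away; the signal mask count is exact."""
        img, truth = synthetic.generate_image(
            shape=(96, 96), salt_density=0.003, rng_seed=4
        )
        res = area_positive(img, threshold=500, despeckle_radius=2, outlier_threshold=2000)
        assert res.pixels == truth.signal_area_px

    def test_despeckle_disabled_equals_plain_threshold_count(self):
        img, truth = synthetic.generate_image(shape=(64, 64), salt_density=0.004, rng_seed=1)
        res = area_positive(img, threshold=500, despeckle_radius=0)
        oracle = int(((img.image > 500) & img.roi_mask()).sum())
        assert res.pixels == oracle
        salt_outside = sum(
            not truth.signal_mask[r, c] for r, c in truth.salt_pixels
        )
        assert res.pixels == truth.signal_area_px + salt_outside

    def test_roi_restricts_the_count(self):
        im = np.full((40, 40), 100, dtype=np.uint16)
        im[0:20, 0:20] = 1000
        roi = np.array([[0, 0], [0, 9.5], [9.5, 9.5], [9.5, 0]])  # 10 x 10 corner
        img = AnnotatedImage(image=im, rois=[roi])
        assert area_positive(img, threshold=500).pixels == 100

    def test_threshold_outside_range_rejected(self):
        img = AnnotatedImage(
            image=np.zeros((8, 8), dtype=np.uint16),
            rois=[np.array([[0, 0], [0, 7], [7, 7], [7, 0]])],
        )
        with pytest.raises(ValueError, match="intensity range"):
            area_positive(img, threshold=10)

    def test_despeckle_touches_only_bright_outliers(self):
        im = np.full((30, 30), 500, dtype=np.uint16)
        im[10, 10] = 60000  # bright outlier: replaced
        im[20, 20] = 0  # dark outlier: untouched (bright-only semantics)
        out = despeckle(im, radius=2, outlier_threshold=1000)
        assert out[10, 10] == 500
        assert out[20, 20] == 0
        assert (out[im == 500] == 500).all()


class TestTTest:
    def test_identical_groups_give_t0_p1(self):
        g = [1.0, 2.0, 3.0, 4.0]
        for variant in ("student", "welch"):
            res = t_test(g, g, variant)
            assert res.t == 0.0
            assert res.p == pytest.approx(1.0)

    def test_student_matches_hand_evaluated_pooled_formula(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([2.0, 3, 4, 5])
        # pooled: var_a = var_b = 5/3; sp2 = 5/3; se = sqrt(5/3 * 1/2)
        se = np.sqrt((5 / 3) * 0.5)
        expect_t = (2.5 - 3.5) / se
        res = t_test(a, b, "student")
        assert res.t == pytest.approx(expect_t, abs=1e-12)
        assert res.df == 6

    def test_swapping_groups_negates_t_keeps_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(loc=0.6, size=5)
        r1 = t_test(a, b, "welch")
        r2 = t_test(b, a, "welch")
        assert r2.t == pytest.approx(-r1.t)
        assert r2.p == pytest.approx(r1.p)

    @pytest.mark.parametrize("variant", ["student", "welch"])
    def test_matches_scipy_on_random_group_pairs(self, variant):
        rng = np.random.default_rng(99)
        for _ in range(100):
            na, nb = rng.integers(2, 12, size=2)
            a = rng.normal(loc=rng.normal(), scale=rng.uniform(0.5, 3), size=na)
            b = rng.normal(loc=rng.normal(), scale=rng.uniform(0.5, 3), size=nb)
            res = t_test(a, b, variant)
            oracle = sps.ttest_ind(a, b, equal_var=(variant == "student"))
            assert res.t == pytest.approx(oracle.statistic, abs=1e-9)
            assert res.p == pytest.approx(oracle.pvalue, abs=1e-9)
            assert res.df == pytest.approx(oracle.df, abs=1e-9)

    def test_welch_df_never_exceeds_pooled_df(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            na, nb = rng.integers(2, 10, size=2)
            a = rng.normal(size=na)
            b = rng.normal(scale=3.0, size=nb)
            res = t_test(a, b, "welch")
            assert res.df <= na + nb - 2 + 1e-12

    def test_zero_variance_unequal_means_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            t_test([1.0, 1.0], [2.0, 2.0], "welch")

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0], [1.0, 2.0], "student")
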