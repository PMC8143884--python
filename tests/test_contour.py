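import numpy as np
import pytest

import lvseg
from lvseg import PipelineConfig, UltrasoundFrame
from lvseg.contour import (
    EndocardialContour,
    WallCurve,
    approach_endocardium,
    build_cavity_mask,
    chord_parameters,
    fill_contour,
    fit_wall,
    fit_wall_constrained,
    mask_binary,
    sample_wall_points,
    segment_endocardium,
    smooth_bspline,
)
from lvseg.errors import (
    ConstraintConflictError,
    GeometryError,
    InsufficientSupportError,
    ValidationError,
)
from lvseg.geometry import ConstraintTriplet
from lvseg.mrf import LabelField


def _const_curve(col, row_range=(5.0, 30.0)):
    mid = 0.5 * (row_range[0] + row_range[1])
    half = 0.5 * (row_range[1] - row_range[0])
    return WallCurve(np.array([0.0, 0.0, 0.0, col]), row_range, mid, half)


class TestSampleWallPoints:
    def test_two_vertical_bars(self):
        # myocardium bars at cols 5..8 and 20..23; inner edges at 8.5 / 19.5
        labels = np.zeros((12, 30), dtype=np.int8)
        labels[:, 5:9] = 1
        labels[:, 20:24] = 1
        cons = ConstraintTriplet(apex=(0.0, 14.0), lower_left=(9.0, 8.0), lower_right=(9.0, 20.0))
        left, right = sample_wall_points(LabelField(labels), cons)
        assert np.all(left[:, 1] == 8.5)
        assert np.all(right[:, 1] == 19.5)
        assert len(left) == len(right) == 10

    def test_empty_field_raises(self):
        labels = LabelField(np.zeros((12, 30), dtype=np.int8))
        cons = ConstraintTriplet(apex=(0.0, 14.0), lower_left=(9.0, 8.0), lower_right=(9.0, 20.0))
        with pytest.raises(InsufficientSupportError):
            sample_wall_points(labels, cons)

    def test_phantom_truth_samples_near_true_walls(self, clean_truth):
        labels = LabelField(clean_truth.myocardium_mask.astype(np.int8))
        left, right = sample_wall_points(labels, clean_truth.constraints)
        spec = clean_truth.spec
        dl = np.abs(spec.left_wall(left[:, 0]) - left[:, 1])
        dr = np.abs(spec.right_wall(right[:, 0]) - right[:, 1])
        assert dl.max() <= 1.0
        assert dr.max() <= 1.0


class TestFitWall:
    def test_exact_cubic_recovery(self):
        rows = np.array([0.0, 1, 2, 3, 4, 5])
        cols = 2 * rows**3 - rows + 5
        curve = fit_wall(np.column_stack([rows, cols]))
        assert np.abs(curve(rows) - cols).max() < 1e-8

    def test_square_system_interpolates(self):
        rows = np.array([0.0, 2.0, 5.0, 9.0])
        cols = np.array([1.0, -3.0, 4.0, 10.0])
        curve = fit_wall(np.column_stack([rows, cols]))
        assert curve.residual_ss < 1e-16
        assert np.abs(curve(rows) - cols).max() < 1e-8

    def test_normal_equations_satisfied(self):
        rng = np.random.default_rng(0)
        rows = np.sort(rng.uniform(0, 100, 40))
        cols = rng.uniform(0, 100, 40)
        curve = fit_wall(np.column_stack([rows, cols]))
        t = (rows - curve.row_mid) / curve.row_half
        B = np.vander(t, 4)
        v = B @ curve.coefficients - cols
        assert np.abs(B.T @ v).max() < 1e-8 * max(1.0, np.abs(cols).max())

    def test_monte_carlo_unbiasedness(self):
        # mean fitted coefficients over noisy replicates approach the truth
        rng = np.random.default_rng(1)
        rows = np.linspace(10, 110, 50)
        true = 40 + 0.5 * rows - 0.01 * rows**2 + 5e-5 * rows**3
        coefs = []
        n_rep = 500
        for _ in range(n_rep):
            cols = true + rng.normal(0, 1.0, rows.size)
            coefs.append(fit_wall(np.column_stack([rows, cols])).coefficients)
        coefs = np.asarray(coefs)
        # truth expressed on the same normalized basis
        ref = fit_wall(np.column_stack([rows, true]))
        se = coefs.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(coefs.mean(axis=0) - ref.coefficients) <= 3 * se + 1e-9)

    def test_rank_deficient_rejected(self):
        pts = np.column_stack([np.full(6, 3.0), np.arange(6.0)])
        with pytest.raises(InsufficientSupportError):
            fit_wall(pts)


class TestFitWallConstrained:
    def _noisy_points(self, seed=0, n=50):
        rng = np.random.default_rng(seed)
        rows = np.linspace(30, 150, n)
        cols = 60 + 0.3 * rows - 2e-3 * rows**2 + rng.normal(0, 1.0, n)
        return np.column_stack([rows, cols])

    def test_inactive_constraints_match_unconstrained(self):
        pts = self._noisy_points()
        free = fit_wall(pts)
        cons = np.array(
            [[40.0, float(free(40.0))], [140.0, float(free(140.0))]]
        )
        forced = fit_wall_constrained(pts, cons)
        rows = np.linspace(30, 150, 37)
        assert np.abs(forced(rows) - free(rows)).max() < 1e-6

    def test_constraints_satisfied_to_tolerance(self):
        pts = self._noisy_points(3)
        cons = np.array([[25.0, 80.0], [155.0, 95.0]])
        forced = fit_wall_constrained(pts, cons)
        assert abs(float(forced(25.0)) - 80.0) < 1e-6
        assert abs(float(forced(155.0)) - 95.0) < 1e-6

    def test_constrained_residual_never_beats_unconstrained(self):
        rng = np.random.default_rng(4)
        for seed in range(20):
            pts = self._noisy_points(seed)
            free = fit_wall(pts)
            cons = np.array(
                [
                    [28.0, float(free(28.0)) + rng.uniform(-5, 5)],
                    [152.0, float(free(152.0)) + rng.uniform(-5, 5)],
                ]
            )
            forced = fit_wall_constrained(pts, cons)
            assert forced.residual_ss >= free.residual_ss - 1e-9

    def test_conflicting_constraints_rejected(self):
        pts = self._noisy_points(5)
        with pytest.raises(ConstraintConflictError):
            fit_wall_constrained(pts, np.array([[40.0, 10.0], [40.0, 50.0]]))


class TestCavityMask:
    def test_rectangle_pixel_count(self):
        cons = ConstraintTriplet(apex=(5, 15), lower_left=(30, 10), lower_right=(30, 20))
        mask = build_cavity_mask(_const_curve(10.0), _const_curve(20.0), cons, (40, 40))
        assert mask.sum() == 26 * 11  # rows 5..30, cols 10..20 inclusive

    def test_single_row_band(self):
        cons = ConstraintTriplet(apex=(29.5, 15), lower_left=(30, 10), lower_right=(30, 20))
        mask = build_cavity_mask(
            _const_curve(10.0, (29.0, 31.0)), _const_curve(20.0, (29.0, 31.0)), cons, (40, 40)
        )
        assert mask[30, 10:21].all()
        assert mask.sum() == 11

    def test_crossing_curves_rejected(self):
        cons = ConstraintTriplet(apex=(5, 15), lower_left=(30, 10), lower_right=(30, 20))
        with pytest.raises(GeometryError, match="row"):
            build_cavity_mask(_const_curve(20.0), _const_curve(10.0), cons, (40, 40))

    def test_matches_phantom_cavity(self, clean_truth):
        spec = clean_truth.spec
        cons = clean_truth.constraints
        rows_l = np.array([spec.apex_point[0], spec.bottom_left[0]])
        mid_l, half_l = rows_l.mean(), np.ptp(rows_l) / 2
        # translate the generating raw-row cubics into normalized WallCurves
        def to_curve(raw):
            t_nodes = np.linspace(-1, 1, 8)
            rows = mid_l + half_l * t_nodes
            coef = np.polyfit(t_nodes, np.polyval(raw, rows), 3)
            return WallCurve(coef, (rows_l[0], rows_l[1]), mid_l, half_l)

        mask = build_cavity_mask(
            to_curve(spec.wall_coeffs_left), to_curve(spec.wall_coeffs_right), cons, clean_truth.frame.shape
        )
        assert lvseg.dice(mask, clean_truth.cavity_mask) >= 0.98


class TestMaskBinary:
    def test_large_dilation_is_identity(self, clean_truth):
        labels = LabelField(clean_truth.myocardium_mask.astype(np.int8))
        out = mask_binary(labels, clean_truth.cavity_mask, dilation=400, min_component=0)
        assert np.array_equal(out.labels, labels.labels)

    def test_speckle_island_removed(self, clean_truth):
        labels = clean_truth.myocardium_mask.astype(np.int8)
        rows = np.nonzero(clean_truth.cavity_mask.any(axis=1))[0]
        r = rows[len(rows) // 2]
        cols = np.nonzero(clean_truth.cavity_mask[r])[0]
        c = cols[len(cols) // 2]
        labels[r, c : c + 3] = 1  # 3-px island at the cavity center
        out = mask_binary(LabelField(labels), clean_truth.cavity_mask, dilation=5, min_component=20)
        assert not out.myocardium_mask[r, c : c + 3].any()

    def test_masking_never_hurts_dice_with_artifacts(self):
        truth = lvseg.render_phantom(lvseg.random_spec(5, artifact_count=4))
        res = lvseg.segment_endocardium(
            truth.frame, truth.constraints, truth.lv_box, PipelineConfig(seed=5)
        )
        gt = truth.myocardium_mask
        d_masked = lvseg.dice(res.labels_masked.myocardium_mask, gt)
        d_raw = lvseg.dice(res.labels.myocardium_mask, gt)
        assert d_masked >= d_raw - 1e-12


class TestApproachEndocardium:
    def test_noise_free_contour_close_to_truth(self, clean_truth):
        res = segment_endocardium(
            clean_truth.frame, clean_truth.constraints, clean_truth.lv_box, PipelineConfig(seed=2)
        )
        pts = res.raw_contour.points
        d = np.array(
            [np.linalg.norm(clean_truth.endocardium.points - p[None, :], axis=1).min() for p in pts]
        )
        assert np.median(d) <= 1.0
        assert d.max() <= 2.0

    def test_constraints_inserted_verbatim(self, clean_truth):
        res = segment_endocardium(
            clean_truth.frame, clean_truth.constraints, clean_truth.lv_box, PipelineConfig(seed=2)
        )
        pts = res.raw_contour.points
        cons = clean_truth.constraints
        assert tuple(pts[0]) == cons.lower_left
        assert tuple(pts[-1]) == cons.lower_right
        assert any(tuple(p) == cons.apex for p in pts)

    def test_no_duplicate_consecutive_vertices(self, clean_truth):
        res = segment_endocardium(
            clean_truth.frame, clean_truth.constraints, clean_truth.lv_box, PipelineConfig(seed=2)
        )
        diffs = np.linalg.norm(np.diff(res.raw_contour.points, axis=0), axis=1)
        assert np.all(diffs > 0)

    def test_empty_cavity_raises(self):
        from lvseg.errors import ExtractionFailureError

        labels = LabelField(np.zeros((20, 20), dtype=np.int8))
        cons = ConstraintTriplet(apex=(2.0, 10.0), lower_left=(15.0, 5.0), lower_right=(15.0, 15.0))
        with pytest.raises(ExtractionFailureError):
            approach_endocardium(labels, cons, np.zeros((20, 20), dtype=bool))


class TestSmoothBspline:
    def test_collinear_points_stay_collinear(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0) + 1])
        out = smooth_bspline(EndocardialContour(pts), smoothing=5.0, n_out=50)
        resid = np.abs(out.points[:, 1] - (2 * out.points[:, 0] + 1))
        assert resid.max() < 1e-6

    def test_zero_smoothing_interpolates_inputs(self):
        rng = np.random.default_rng(6)
        pts = np.column_stack([np.linspace(0, 20, 9), rng.uniform(0, 5, 9)])
        u = chord_parameters(pts)
        out = smooth_bspline(EndocardialContour(pts), smoothing=0.0, params=u)
        assert np.abs(out.points - pts).max() < 1e-6

    def test_endpoints_preserved_exactly(self):
        rng = np.random.default_rng(7)
        pts = np.column_stack([np.linspace(0, 30, 15), rng.uniform(0, 8, 15)])
        out = smooth_bspline(EndocardialContour(pts), smoothing=10.0, n_out=40)
        assert tuple(out.points[0]) == tuple(pts[0])
        assert tuple(out.points[-1]) == tuple(pts[-1])

    def test_zigzag_noise_reduced(self):
        zig = np.column_stack(
            [np.linspace(0, 20, 21), 1.0 + 2.0 * np.where(np.arange(21) % 2 == 0, 1.0, -1.0)]
        )
        out = smooth_bspline(EndocardialContour(zig), smoothing=2.0 * len(zig), n_out=100)
        raw_mad = np.abs(zig[:, 1] - 1.0).mean()
        smooth_mad = np.abs(out.points[:, 1] - 1.0).mean()
        assert smooth_mad < raw_mad

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            smooth_bspline(EndocardialContour(np.zeros((3, 2)) + np.arange(3)[:, None]))


class TestEndToEnd:
    def test_noise_free_pipeline_mad_below_one_px(self, clean_truth):
        res = segment_endocardium(
            clean_truth.frame, clean_truth.constraints, clean_truth.lv_box, PipelineConfig(seed=0)
        )
        assert lvseg.mad(res.contour.points, clean_truth.endocardium.points) <= 1.0

    def test_pipeline_deterministic(self, speckled_truth):
        cons = lvseg.perturb_constraints(speckled_truth, 2.0, 77)
        a = segment_endocardium(
            speckled_truth.frame, cons, speckled_truth.lv_box, PipelineConfig(seed=9)
        )
        b = segment_endocardium(
            speckled_truth.frame, cons, speckled_truth.lv_box, PipelineConfig(seed=9)
        )
        assert np.array_equal(a.contour.points, b.contour.points)
        assert np.array_equal(a.predicted_cavity, b.predicted_cavity)

    def test_wall_recovery_from_in_family_phantoms(self):
        worst = 0.0
        for seed in range(5):
            spec = lvseg.random_spec(seed, speckle_shape=None, artifact_count=0)
            truth = lvseg.render_phantom(spec)
            res = segment_endocardium(
                truth.frame, truth.constraints, truth.lv_box, PipelineConfig(seed=seed)
            )
            rows = np.arange(spec.apex_point[0], spec.bottom_left[0], 0.5)
            worst = max(
                worst,
                np.abs(res.left_wall(rows) - spec.left_wall(rows)).max(),
                np.abs(res.right_wall(rows) - spec.right_wall(rows)).max(),
            )
        assert worst <= 0.5

    def test_dice_degrades_monotonically_with_speckle(self):
        medians = []
        for shape in (100.0, 30.0, 10.0, 4.0):
            dices = []
            for seed in range(6):
                truth = lvseg.render_phantom(
                    lvseg.random_spec(seed, speckle_shape=shape, artifact_count=0)
                )
                res = segment_endocardium(
                    truth.frame, truth.constraints, truth.lv_box, PipelineConfig(seed=seed)
                )
                dices.append(lvseg.dice(res.predicted_cavity, truth.cavity_mask))
            medians.append(np.median(dices))
        assert all(a >= b - 0.005 for a, b in zip(medians, medians[1:]))

    def test_fill_contour_matches_cavity(self, clean_truth):
        filled = fill_contour(clean_truth.endocardium, clean_truth.frame.shape)
        assert lvseg.dice(filled, clean_truth.cavity_mask) >= 0.97
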