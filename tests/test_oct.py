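"""Tests of the graph-based OCT segmentation and thickness measurement."""

import numpy as np
import pytest

from retinad import oct, synth
from retinad.exceptions import (
    CorrectionBudgetWarning,
    InvalidParameterError,
    LowContrastWarning,
    PartialSummaryWarning,
    SegmentationError,
)
from retinad.types import BoundarySet, BScan

from conftest import brute_force_min_path


def step_image(h=40, w=40, row=20, low=0.1, high=0.9):
    img = np.full((h, w), low)
    img[row:, :] = high
    return img


class TestGradientMap:
    def test_step_image_peak_on_step_row(self):
        g = oct.gradient_map(step_image(), "dark-to-light")
        assert np.all(np.argmax(g, axis=0) == 19)  # centre convention: 20-0.5
        assert g.max() == 1.0 and g.min() >= 0.0

    def test_inverted_image_opposite_polarity_identical(self):
        img = step_image()
        a = oct.gradient_map(img, "dark-to-light")
        b = oct.gradient_map(img.max() - img, "light-to-dark")
        assert np.allclose(a, b)

    def test_constant_image_warns_low_contrast(self):
        with pytest.warns(LowContrastWarning):
            g = oct.gradient_map(np.full((40, 40), 3.0), "dark-to-light")
        assert np.all(g == 0.0)

    def test_phantom_columnwise_argmax_near_truth(self):
        p = synth.BScanParams.from_thickness(31.2, 54.7, speckle_sd=0.0)
        scan, truth = synth.simulate_bscan(p, 3)
        g = oct.gradient_map(scan, "dark-to-light")
        argmax = np.argmax(g, axis=0)
        assert np.max(np.abs(argmax - truth.ilm)) <= 1.0


class TestTraceBoundary:
    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(50):
            h, w = rng.integers(2, 8, size=2)
            g = rng.random((h, w))
            path = oct.trace_boundary(g)
            cost, best = brute_force_min_path(g)
            assert np.array_equal(path, best)

    def test_uniform_weights_flat_top_path(self):
        path = oct.trace_boundary(np.full((6, 6), 0.3))
        assert np.array_equal(path, np.zeros(6, dtype=int))

    def test_step_gradient_follows_step_row(self):
        g = oct.gradient_map(step_image(), "dark-to-light")
        assert np.all(oct.trace_boundary(g) == 19)

    def test_allowed_mask_respected(self):
        g = oct.gradient_map(step_image(), "dark-to-light")
        allowed = np.zeros_like(g, dtype=bool)
        allowed[30:, :] = True
        path = oct.trace_boundary(g, allowed=allowed)
        assert np.all(path >= 30)

    def test_empty_column_in_mask_raises(self):
        g = np.random.default_rng(0).random((6, 6))
        allowed = np.ones_like(g, dtype=bool)
        allowed[:, 3] = False
        with pytest.raises(SegmentationError):
            oct.trace_boundary(g, allowed=allowed)


class TestSegmentRetina:
    def test_constant_image_fails(self):
        scan = BScan(np.full((64, 64), 0.5), axial_px_um=3.9)
        with pytest.raises(SegmentationError):
            oct.segment_retina(scan)

    def test_default_phantom_mean_error_below_one_px(self):
        """20-seed phantom study: MAE <= 1 px, max error <= 3 px."""
        maes, maxes = [], []
        for seed in range(20):
            p = synth.BScanParams.from_thickness(31.2, 54.7)
            scan, truth = synth.simulate_bscan(p, seed)
            got = oct.segment_retina(scan)
            err = np.abs(got.as_array() - truth.as_array())
            maes.append(err.mean())
            maxes.append(err.max())
        assert np.mean(maes) <= 1.0
        assert max(maxes) <= 3.0

    def test_boundaries_always_ordered(self):
        for seed in range(5):
            p = synth.BScanParams.from_thickness(28.5, 51.0)
            scan, _ = synth.simulate_bscan(p, seed)
            got = oct.segment_retina(scan)
            got.validate_ordering()  # raises on violation

    def test_subpixel_refinement_stays_close(self):
        p = synth.BScanParams.from_thickness(31.2, 54.7, speckle_sd=0.0)
        scan, truth = synth.simulate_bscan(p, 11)
        got = oct.segment_retina(scan, subpixel=True)
        err = np.abs(got.as_array() - truth.as_array())
        assert err.mean() <= 0.5


class TestCorrections:
    @pytest.fixture
    def bounds(self):
        w = 50
        return BoundarySet(
            ilm=np.full(w, 10.0), inl_opl=np.full(w, 20.0), rpe_base=np.full(w, 35.0)
        )

    def test_empty_corrections_identity(self, bounds):
        out = oct.apply_corrections(bounds, [])
        assert np.array_equal(out.as_array(), bounds.as_array())
        assert out.corrected_fraction == 0.0

    def test_budget_warning_above_five_percent(self, bounds):
        # 3 of 50 columns corrected = 6 %
        with pytest.warns(CorrectionBudgetWarning):
            out = oct.apply_corrections(bounds, [("ilm", (0, 3), 11.0)])
        assert out.corrected_fraction == pytest.approx(0.06)

    def test_within_budget_no_warning(self, bounds, recwarn):
        out = oct.apply_corrections(bounds, [("ilm", (0, 2), 11.0)])
        assert out.corrected_fraction == pytest.approx(0.04)
        assert not any(
            isinstance(w.message, CorrectionBudgetWarning) for w in recwarn.list
        )

    def test_ordering_violation_rejected(self, bounds):
        with pytest.raises(InvalidParameterError, match="ordering"):
            oct.apply_corrections(bounds, [("inl_opl", (5, 10), 40.0)])

    def test_out_of_image_rejected(self, bounds):
        with pytest.raises(InvalidParameterError):
            oct.apply_corrections(bounds, [("ilm", (0, 2), -3.0)], image_height=64)


class TestThickness:
    def make_scan(self, h=64, w=64, axial=3.9):
        img = np.zeros((h, w))
        img[20:, :] = 1.0
        return BScan(img, axial_px_um=axial)

    def test_eight_pixels_at_device_scale(self):
        """8 px × 3.9 μm/px = 31.2 μm, the printed young inner thickness."""
        w = 64
        b = BoundarySet(
            ilm=np.full(w, 12.0), inl_opl=np.full(w, 20.0), rpe_base=np.full(w, 34.0)
        )
        inner, outer = oct.thickness(b, self.make_scan())
        assert inner == pytest.approx(8 * 3.9)
        assert outer == pytest.approx(14 * 3.9)

    def test_axial_scale_linearity(self):
        w = 64
        b = BoundarySet(
            ilm=np.full(w, 12.0), inl_opl=np.full(w, 20.0), rpe_base=np.full(w, 34.0)
        )
        i1, o1 = oct.thickness(b, self.make_scan(axial=3.9))
        i2, o2 = oct.thickness(b, self.make_scan(axial=7.8))
        assert i2 == pytest.approx(2 * i1) and o2 == pytest.approx(2 * o1)

    def test_onh_columns_excluded(self):
        w = 64
        ilm = np.full(w, 12.0)
        inl = np.full(w, 20.0)
        inl[28:36] = 30.0  # distorted at the centre; excluded by onh_cols
        b = BoundarySet(ilm=ilm, inl_opl=inl, rpe_base=np.full(w, 40.0))
        scan = BScan(self.make_scan().image, axial_px_um=3.9, onh_cols=(28, 36))
        inner, _ = oct.thickness(b, scan)
        assert inner == pytest.approx(8 * 3.9)

    def test_all_columns_excluded_raises(self):
        w = 64
        b = BoundarySet(
            ilm=np.full(w, 12.0), inl_opl=np.full(w, 20.0), rpe_base=np.full(w, 34.0)
        )
        scan = BScan(self.make_scan().image, axial_px_um=3.9, onh_cols=(0, w))
        with pytest.raises(InvalidParameterError):
            oct.thickness(b, scan)


class TestNormalizeIntensity:
    def build(self, inner_val=0.45, rpe_val=0.9):
        h, w = 64, 64
        img = np.full((h, w), 0.05)
        img[12:20, :] = inner_val
        img[20:31, :] = 0.3
        img[31:34, :] = rpe_val
        bounds = BoundarySet(
            ilm=np.full(w, 12.0), inl_opl=np.full(w, 20.0), rpe_base=np.full(w, 34.0)
        )
        return BScan(img, axial_px_um=3.9), bounds

    def test_half_ratio_construction(self):
        scan, bounds = self.build(inner_val=0.45, rpe_val=0.9)
        inner_n, _ = oct.normalize_intensity(scan, bounds)
        assert inner_n == pytest.approx(0.5, abs=0.01)

    def test_global_gain_invariance(self):
        scan, bounds = self.build()
        a = oct.normalize_intensity(scan, bounds)
        scaled = BScan(scan.image * 3.0, axial_px_um=3.9)
        b = oct.normalize_intensity(scaled, bounds)
        assert a == pytest.approx(b)

    def test_random_per_scan_gain_invariance(self, rng):
        p = synth.BScanParams.from_thickness(31.2, 54.7)
        scan, _ = synth.simulate_bscan(p, 2)
        bounds = oct.segment_retina(scan)
        base = oct.normalize_intensity(scan, bounds)
        for _ in range(5):
            gain = rng.uniform(0.5, 4.0)
            scaled = BScan(scan.image * gain, axial_px_um=3.9, onh_cols=scan.onh_cols)
            assert oct.normalize_intensity(scaled, bounds) == pytest.approx(base)

    def test_zero_rpe_band_raises(self):
        scan, bounds = self.build(rpe_val=0.0)
        with pytest.raises(InvalidParameterError):
            oct.normalize_intensity(scan, bounds)


class TestSummarizeEye:
    def test_five_identical_phantoms_equal_single(self):
        p = synth.BScanParams.from_thickness(31.2, 54.7)
        scan, _ = synth.simulate_bscan(p, 4)
        res5 = oct.summarize_eye([scan] * 5)
        res1 = oct.summarize_eye([scan])
        assert res5.inner_um == pytest.approx(res1.inner_um)
        assert res5.n_scans_used == 5

    def test_mean_is_arithmetic(self):
        scans = []
        for inner in (30.0, 30.0, 31.0, 31.0, 31.0):
            p = synth.BScanParams.from_thickness(
                inner, 54.0, speckle_sd=0.0, boundary_smoothness=0.0, onh_dip_px=0.0,
                ilm_depth_um=30.5 * 3.9,
            )
            scans.append(synth.simulate_bscan(p, 0)[0])
        res = oct.summarize_eye(scans)
        per_scan = [
            oct.thickness(oct.segment_retina(s), s)[0] for s in scans
        ]
        assert res.inner_um == pytest.approx(np.mean(per_scan))

    def test_failing_scan_dropped_with_warning(self):
        p = synth.BScanParams.from_thickness(31.2, 54.7)
        good, _ = synth.simulate_bscan(p, 4)
        bad = BScan(np.full((64, 64), 0.5), axial_px_um=3.9)
        with pytest.warns(PartialSummaryWarning):
            res = oct.summarize_eye([good, bad, good])
        assert res.n_scans_used == 2

    def test_all_failing_raises(self):
        bad = BScan(np.full((64, 64), 0.5), axial_px_um=3.9)
        with pytest.raises(SegmentationError):
            oct.summarize_eye([bad])

    def test_full_default_eye_close_to_truth(self):
        p = synth.BScanParams.from_thickness(31.2, 54.7)
        scans = [synth.simulate_bscan(p, s)[0] for s in range(5)]
        res = oct.summarize_eye(scans)
        assert res.inner_um == pytest.approx(31.2, abs=3.9)
        assert res.outer_um == pytest.approx(54.7, abs=3.9)
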