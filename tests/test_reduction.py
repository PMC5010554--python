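"""Reduction identities: ring integration, normalization, subtraction, merging."""

import numpy as np
import pytest

from trxs.models import DifferenceCurve, ScatteringCurve
from trxs.reduction import (
    AcquisitionTriplet,
    DetectorImage,
    integrate_rings,
    merge_detectors,
    normalize_window,
    pixel_q_map,
    subtract_heat,
    subtract_laser_off,
)
from trxs.synthetic import make_detector_image


def flat_image(value=5.0, shape=(64, 64), **kw):
    return DetectorImage(
        data=np.full(shape, value),
        center_px=((shape[0] - 1) / 2, (shape[1] - 1) / 2),
        pixel_mm=1.0,
        distance_mm=200.0,
        wavelength_nm=0.1,
        **kw,
    )


class TestIntegrateRings:
    def test_uniform_image_gives_flat_curve(self):
        curve = integrate_rings(flat_image(5.0), n_bins=30)
        np.testing.assert_allclose(curve.intensity, 5.0, rtol=1e-12)

    def test_radial_paint_round_trip(self):
        img = flat_image(0.0)
        q = pixel_q_map(img)
        img.data = np.exp(-((q - q.max() / 2) ** 2) / (0.1 * q.max()) ** 2)
        curve = integrate_rings(img, n_bins=80)
        expected = np.exp(-((curve.q - q.max() / 2) ** 2) / (0.1 * q.max()) ** 2)
        assert np.max(np.abs(curve.intensity - expected)) < 0.02

    def test_fully_masked_rejected(self):
        img = flat_image(1.0, mask=np.ones((64, 64), dtype=bool))
        with pytest.raises(ValueError, match="valid pixels"):
            integrate_rings(img)

    def test_masked_pixels_do_not_bias_mean(self):
        img = flat_image(3.0)
        mask = np.zeros(img.data.shape, dtype=bool)
        mask[::3, ::5] = True
        img_masked = flat_image(3.0, mask=mask)
        curve = integrate_rings(img_masked, n_bins=20)
        np.testing.assert_allclose(curve.intensity, 3.0, rtol=1e-12)

    def test_center_outside_image_rejected(self):
        img = flat_image(1.0)
        img.center_px = (500.0, 10.0)
        with pytest.raises(ValueError, match="center"):
            integrate_rings(img)


class TestNormalizeWindow:
    q = np.linspace(1.0, 20.0, 100)

    def test_constant_curve_becomes_one(self):
        curve = ScatteringCurve(q=self.q, intensity=np.full(100, 5.0))
        out = normalize_window(curve)
        np.testing.assert_allclose(out.intensity, 1.0)

    def test_window_mean_is_one_after(self):
        rng = np.random.default_rng(0)
        curve = ScatteringCurve(q=self.q, intensity=rng.uniform(1, 9, 100))
        out = normalize_window(curve, window=(14.0, 16.0))
        sel = (self.q >= 14.0) & (self.q <= 16.0)
        assert out.intensity[sel].mean() == pytest.approx(1.0, rel=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        curve = ScatteringCurve(q=self.q, intensity=rng.uniform(1, 9, 100))
        once = normalize_window(curve)
        twice = normalize_window(once)
        np.testing.assert_allclose(twice.intensity, once.intensity, rtol=1e-14)

    def test_empty_window_rejected(self):
        curve = ScatteringCurve(q=np.linspace(0.1, 2, 10),
                                intensity=np.ones(10))
        with pytest.raises(ValueError, match="window"):
            normalize_window(curve)  # default 14–16 nm⁻¹ misses this grid


class TestSubtractLaserOff:
    q = np.linspace(0.1, 5, 50)

    def _curve(self, vals):
        return ScatteringCurve(q=self.q, intensity=np.asarray(vals, float))

    def test_null_experiment(self):
        s = self._curve(np.linspace(1, 3, 50))
        out = subtract_laser_off(AcquisitionTriplet(s, s, s))
        np.testing.assert_allclose(out.delta, 0.0, atol=1e-15)

    def test_zero_reference(self):
        on = self._curve(np.linspace(1, 3, 50))
        zero = self._curve(np.zeros(50))
        out = subtract_laser_off(AcquisitionTriplet(zero, on, zero))
        np.testing.assert_allclose(out.delta, on.intensity)

    def test_linear_drift_cancelled(self):
        base = np.linspace(1, 3, 50)
        pre = self._curve(base)
        post = self._curve(base + 0.4)  # drifted by a constant offset
        on = self._curve(base + 0.2)    # on the midline of the drift
        out = subtract_laser_off(AcquisitionTriplet(pre, on, post))
        np.testing.assert_allclose(out.delta, 0.0, atol=1e-14)

    def test_linearity_in_inputs(self):
        rng = np.random.default_rng(3)
        a, b, c = (self._curve(rng.uniform(1, 2, 50)) for _ in range(3))
        out1 = subtract_laser_off(AcquisitionTriplet(a, b, c))
        scaled = AcquisitionTriplet(
            self._curve(2 * a.intensity), self._curve(2 * b.intensity),
            self._curve(2 * c.intensity))
        out2 = subtract_laser_off(scaled)
        np.testing.assert_allclose(out2.delta, 2 * out1.delta, rtol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = self._curve(np.ones(50))
        b = ScatteringCurve(q=self.q + 0.01, intensity=np.ones(50))
        with pytest.raises(ValueError, match="grid"):
            AcquisitionTriplet(a, b, a)


class TestMergeDetectors:
    def test_identical_curves_scale_one(self):
        q = np.linspace(0.1, 10, 100)
        c = ScatteringCurve(q=q, intensity=np.exp(-q / 3))
        merged, scale = merge_detectors(c, c)
        assert scale == pytest.approx(1.0, rel=1e-12)
        np.testing.assert_allclose(merged.intensity, c.intensity)

    def test_halved_overlap_gives_scale_two(self):
        # linear profile: interpolation between grids is then exact, so the
        # recovered scale must be exactly 2 for a halved wide-angle curve
        q_small = np.linspace(0.05, 6.7, 120)
        q_wide = np.linspace(5.2, 27.5, 200)
        profile = lambda q: 30.0 - q
        small = ScatteringCurve(q=q_small, intensity=profile(q_small))
        wide = ScatteringCurve(q=q_wide, intensity=0.5 * profile(q_wide))
        merged, scale = merge_detectors(small, wide)
        assert scale == pytest.approx(2.0, rel=1e-10)
        assert np.all(np.diff(merged.q) > 0)

    def test_noisy_overlap_matches_closed_form_ratio(self):
        rng = np.random.default_rng(4)
        # small-angle grid is finer inside the overlap, so the scale is fit
        # on it with the wide-angle curve interpolated across
        q_small = np.linspace(0.1, 7, 160)
        q_wide = np.linspace(5.0, 25, 60)
        small = ScatteringCurve(q=q_small,
                                intensity=5 + rng.uniform(0, 1, 160))
        wide = ScatteringCurve(q=q_wide, intensity=2 + rng.uniform(0, 1, 60))
        _, scale = merge_detectors(small, wide)
        lo, hi = 5.0, 7.0
        sel = (q_small >= lo) & (q_small <= hi)
        s = small.intensity[sel]
        w = np.interp(q_small[sel], q_wide, wide.intensity)
        assert scale == pytest.approx(float(s @ w / (w @ w)), rel=1e-8)

    def test_exclusive_ranges_preserved(self):
        q_small = np.linspace(0.1, 7, 80)
        q_wide = np.linspace(5.0, 25, 150)
        small = ScatteringCurve(q=q_small, intensity=np.full(80, 4.0))
        wide = ScatteringCurve(q=q_wide, intensity=np.full(150, 2.0))
        merged, scale = merge_detectors(small, wide)
        mid = 0.5 * (5.0 + 7.0)
        low = merged.q <= mid
        np.testing.assert_allclose(
            merged.intensity[low],
            np.interp(merged.q[low], q_small, small.intensity))
        np.testing.assert_allclose(merged.intensity[~low], scale * 2.0)

    def test_no_overlap_rejected(self):
        a = ScatteringCurve(q=np.linspace(0.1, 2, 20), intensity=np.ones(20))
        b = ScatteringCurve(q=np.linspace(5, 9, 20), intensity=np.ones(20))
        with pytest.raises(ValueError, match="overlap"):
            merge_detectors(a, b)


class TestSubtractHeat:
    q = np.linspace(0.1, 3.0, 60)

    def _heat(self):
        # thermal-expansion-like pattern, non-zero in the 1–2 nm⁻¹ fit window
        return DifferenceCurve(q=self.q, delta=np.sin(self.q) * np.exp(-self.q / 4))

    def test_pure_heat_removed(self):
        heat = self._heat()
        curve = DifferenceCurve(q=self.q, delta=3.0 * heat.delta)
        out, c = subtract_heat(curve, heat)
        assert c == pytest.approx(3.0, rel=1e-12)
        np.testing.assert_allclose(out.delta, 0.0, atol=1e-13)

    def test_orthogonal_signal_unchanged(self):
        heat = self._heat()
        sel = (self.q >= 1.0) & (self.q <= 2.0)
        signal = np.zeros(self.q.size)
        signal[~sel] = 1.0  # entirely outside the fit window
        curve = DifferenceCurve(q=self.q, delta=signal)
        out, c = subtract_heat(curve, heat)
        assert c == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(out.delta, signal, atol=1e-12)

    def test_mixture_recovery(self):
        heat = self._heat()
        rng = np.random.default_rng(5)
        structural = np.cos(2.5 * self.q) / (1 + self.q)
        # remove the heat-like component of the structural signal over the
        # window so the target is identifiable, as in a real decomposition
        sel = (self.q >= 1.0) & (self.q <= 2.0)
        h = heat.delta[sel]
        structural = structural - (structural[sel] @ h / (h @ h)) * heat.delta
        curve = DifferenceCurve(q=self.q, delta=structural + 1.5 * heat.delta)
        out, c = subtract_heat(curve, heat)
        assert c == pytest.approx(1.5, rel=1e-10)
        peak = np.max(np.abs(structural))
        assert np.max(np.abs(out.delta - structural)) < 0.02 * peak

    def test_residual_orthogonal_to_heat_over_window(self):
        heat = self._heat()
        rng = np.random.default_rng(6)
        curve = DifferenceCurve(q=self.q, delta=rng.standard_normal(self.q.size))
        out, _ = subtract_heat(curve, heat)
        sel = (self.q >= 1.0) & (self.q <= 2.0)
        assert abs(out.delta[sel] @ heat.delta[sel]) < 1e-10

    def test_zero_heat_in_window_rejected(self):
        heat = DifferenceCurve(q=self.q, delta=np.zeros(self.q.size))
        curve = DifferenceCurve(q=self.q, delta=np.ones(self.q.size))
        with pytest.raises(ValueError, match="heat"):
            subtract_heat(curve, heat)


class TestDetectorImageRoundTrip:
    def test_noiseless_paint_then_integrate(self):
        q = np.linspace(0.2, 5.0, 60)
        target = ScatteringCurve(q=q, intensity=10.0 / (1.0 + q ** 2))
        image, _ = make_detector_image(target, shape=(256, 256))
        curve = integrate_rings(image, n_bins=60)
        # compare over the q range the detector actually covers (the masked
        # border trims the extreme rings)
        covered = (q >= curve.q.min()) & (q <= curve.q.max())
        recovered = np.interp(q[covered], curve.q, curve.intensity)
        assert np.max(np.abs(recovered - target.intensity[covered])
                      / target.intensity[covered]) < 0.02
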