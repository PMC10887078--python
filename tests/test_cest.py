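"""WASSR B0 fitting, double-angle B1, correction and asymmetry mapping."""

import numpy as np
import pytest

from glucest.bloch import GLU_AMINE_POOL, WATER_POOL, simulate_zspectrum
from glucest.cest import (B1LookupCorrector, FieldMaps, ZSpectrumSeries,
                          compute_b1_map, compute_glucest_map,
                          correct_zspectrum, fit_wassr_b0,
                          mtr_asymmetry_curve)
from glucest.phantom import forward_zspectrum_series


def _single_voxel_series(z, offsets, s0=1000.0):
    return ZSpectrumSeries(data=z[None, None, :] * s0, offsets=offsets,
                           reference=np.full((1, 1), s0),
                           mask=np.ones((1, 1), dtype=bool))


def _wassr_series(schedule, b0_shift, b1_scale=1.0, pools=()):
    # WASSR runs at its own (low) saturation power
    from glucest.cest import _wassr_view
    offs = schedule.wassr_offsets
    z = simulate_zspectrum(list(pools), WATER_POOL, _wassr_view(schedule),
                           offsets=offs, b0_shift=b0_shift,
                           b1_scale=b1_scale)
    return _single_voxel_series(z, offs)


class TestWassrB0:
    @pytest.mark.parametrize("shift", [0.0, 0.12, -0.12, 0.3])
    def test_imposed_shift_recovered(self, schedule, shift):
        series = _wassr_series(schedule, shift)
        b0, valid = fit_wassr_b0(series)
        assert valid[0, 0]
        assert abs(b0[0, 0] - shift) < 0.01

    def test_boundary_shift_flagged_or_recovered(self, schedule):
        series = _wassr_series(schedule, 0.75)
        b0, valid = fit_wassr_b0(series)
        assert (not valid[0, 0]) or abs(b0[0, 0] - 0.75) < 0.05

    def test_noiseless_map_accuracy(self, noiseless_acquisition):
        ph = noiseless_acquisition["phantom"]
        b0, valid = fit_wassr_b0(noiseless_acquisition["wassr"])
        err = np.abs(b0 - ph.b0_offset_map)[valid]
        assert valid.sum() > 0.95 * ph.brain_mask.sum()
        assert err.max() <= 0.01

    def test_snr50_accuracy(self, noiseless_acquisition, schedule):
        """At SNR 50 the bulk (95th percentile) B0 error stays below half
        the 0.05 ppm WASSR step."""
        ph = noiseless_acquisition["phantom"]
        fr = noiseless_acquisition["fractions"]
        rng = np.random.default_rng(2024)
        noisy = forward_zspectrum_series(ph, schedule, fr, "wassr",
                                         noise_sd=0.02, rng=rng)
        b0, valid = fit_wassr_b0(noisy)
        err = np.abs(b0 - ph.b0_offset_map)[valid]
        assert np.percentile(err, 95) <= 0.025

    def test_symmetry_method_agrees(self, schedule):
        series = _wassr_series(schedule, 0.1)
        b0_l, _ = fit_wassr_b0(series, method="lorentzian")
        b0_s, _ = fit_wassr_b0(series, method="symmetry")
        assert abs(b0_l[0, 0] - b0_s[0, 0]) < 0.01

    def test_too_few_offsets_rejected(self):
        offs = np.array([-0.1, 0.0, 0.1])
        with pytest.raises(ValueError, match="7"):
            fit_wassr_b0(_single_voxel_series(np.ones(3), offs))

    def test_asymmetric_grid_rejected(self):
        offs = np.arange(-0.5, 0.81, 0.05)
        z = np.ones(offs.size)
        with pytest.raises(ValueError, match="symmetric"):
            fit_wassr_b0(_single_voxel_series(z, offs))


class TestDoubleAngleB1:
    def test_ideal_identity(self):
        s30 = np.full((2, 2), 100.0)
        s60 = 2 * s30 * np.cos(np.radians(30.0))
        b1, valid = compute_b1_map(s30, s60)
        assert np.allclose(b1, 1.0)
        s60 = 2 * s30 * np.cos(np.radians(36.0))
        b1, _ = compute_b1_map(s30, s60)
        assert np.allclose(b1, 1.2)

    def test_map_recovery_from_phantom(self, noiseless_acquisition):
        ph = noiseless_acquisition["phantom"]
        b1, valid = compute_b1_map(*noiseless_acquisition["b1_pair"],
                                   mask=ph.brain_mask)
        err = np.abs(b1 - ph.b1_scale_map)[valid]
        assert err.max() < 1e-3

    def test_zero_signal_invalid(self):
        s30 = np.zeros((1, 1))
        s60 = np.zeros((1, 1))
        _, valid = compute_b1_map(s30, s60)
        assert not valid[0, 0]


class TestCorrection:
    def test_identity_correction(self, schedule):
        offs = schedule.cest_offsets
        z = simulate_zspectrum([GLU_AMINE_POOL], WATER_POOL, schedule)
        series = _single_voxel_series(z, offs)
        fields = FieldMaps(np.zeros((1, 1)), np.ones((1, 1)),
                           np.ones((1, 1), dtype=bool))
        corr = correct_zspectrum(series, fields)
        assert np.allclose(corr.data, series.data, atol=1e-6 * 1000)

    def test_b0_shift_corrected(self, schedule, calibrated_fractions):
        """A +0.3 ppm shifted spectrum, corrected, reproduces the
        unshifted asymmetry within 0.05 percentage points."""
        pool = GLU_AMINE_POOL.with_fraction(
            calibrated_fractions["brain_4.0"])
        offs = schedule.cest_offsets
        shifted = simulate_zspectrum([pool], WATER_POOL, schedule,
                                     b0_shift=0.3)
        nominal = simulate_zspectrum([pool], WATER_POOL, schedule)
        series = _single_voxel_series(shifted, offs)
        fields = FieldMaps(np.full((1, 1), 0.3), np.ones((1, 1)),
                           np.ones((1, 1), dtype=bool))
        corr = correct_zspectrum(series, fields)
        g = compute_glucest_map(corr).values[0, 0]
        ref = compute_glucest_map(
            _single_voxel_series(nominal, offs)).values[0, 0]
        assert abs(g - ref) < 0.05

    def test_b1_lookup_correction(self, schedule, calibrated_fractions):
        """Contrast measured at B1 = 0.9, corrected via the forward-model
        lookup, lands within 0.1 pp of the nominal-B1 contrast."""
        pool = GLU_AMINE_POOL.with_fraction(
            calibrated_fractions["brain_4.0"])
        offs = schedule.cest_offsets
        low_b1 = simulate_zspectrum([pool], WATER_POOL, schedule,
                                    b1_scale=0.9)
        nominal = simulate_zspectrum([pool], WATER_POOL, schedule)
        corrector = B1LookupCorrector([pool], WATER_POOL, schedule)
        series = _single_voxel_series(low_b1, offs)
        fields = FieldMaps(np.zeros((1, 1)), np.full((1, 1), 0.9),
                           np.ones((1, 1), dtype=bool))
        corr = correct_zspectrum(series, fields, b1_corrector=corrector)
        g = compute_glucest_map(corr).values[0, 0]
        ref = compute_glucest_map(
            _single_voxel_series(nominal, offs)).values[0, 0]
        assert abs(g - ref) < 0.1

    def test_out_of_support_offset_nan(self, schedule):
        offs = schedule.cest_offsets
        z = simulate_zspectrum([], WATER_POOL, schedule)
        series = _single_voxel_series(z, offs)
        fields = FieldMaps(np.full((1, 1), 0.4), np.ones((1, 1)),
                           np.ones((1, 1), dtype=bool))
        corr = correct_zspectrum(series, fields)
        # +6 ppm needs a sample at 6.4 ppm, outside the sweep
        assert np.isnan(corr.data[0, 0, np.argmax(corr.offsets)])


class TestGlucestMap:
    def test_printed_formula(self):
        offs = np.array([3.0, -3.0])
        series = ZSpectrumSeries(
            data=np.array([[[0.57, 0.60]]]), offsets=offs,
            reference=np.ones((1, 1)), mask=np.ones((1, 1), bool))
        g = compute_glucest_map(series)
        assert g.values[0, 0] == pytest.approx(5.0, abs=1e-12)

    def test_symmetric_signal_zero(self):
        offs = np.array([3.0, -3.0])
        series = ZSpectrumSeries(
            data=np.array([[[0.6, 0.6]]]), offsets=offs,
            reference=np.ones((1, 1)), mask=np.ones((1, 1), bool))
        assert compute_glucest_map(series).values[0, 0] == 0.0

    @pytest.mark.parametrize("scale", [0.5, 3.7, 120.0])
    def test_scale_invariance(self, schedule, scale):
        """Multiplying the series and S0 by any c > 0 leaves the map
        unchanged."""
        z = simulate_zspectrum([GLU_AMINE_POOL], WATER_POOL, schedule)
        a = _single_voxel_series(z, schedule.cest_offsets, s0=1000.0)
        b = _single_voxel_series(z, schedule.cest_offsets, s0=1000.0 * scale)
        ga = compute_glucest_map(a).values[0, 0]
        gb = compute_glucest_map(b).values[0, 0]
        assert ga == pytest.approx(gb, rel=1e-12)

    def test_small_denominator_flagged(self):
        offs = np.array([3.0, -3.0])
        series = ZSpectrumSeries(
            data=np.array([[[0.001, 0.005]]]), offsets=offs,
            reference=np.ones((1, 1)), mask=np.ones((1, 1), bool))
        g = compute_glucest_map(series)
        assert not g.valid[0, 0]
        assert np.isnan(g.values[0, 0])

    def test_missing_label_offset_raises(self, schedule):
        offs = np.array([2.0, -2.0])
        series = ZSpectrumSeries(
            data=np.ones((1, 1, 2)), offsets=offs,
            reference=np.ones((1, 1)), mask=np.ones((1, 1), bool))
        with pytest.raises(ValueError, match="ppm"):
            compute_glucest_map(series)


class TestMTRAsymCurve:
    def test_symmetric_spectrum_all_zero(self, schedule):
        z = simulate_zspectrum([], WATER_POOL, schedule)
        series = _single_voxel_series(z, schedule.cest_offsets)
        _, curve = mtr_asymmetry_curve(series, np.ones((1, 1), bool))
        assert np.all(np.abs(curve) < 1e-9)

    def test_matches_map_at_label_offset(self, noiseless_acquisition):
        ph = noiseless_acquisition["phantom"]
        cest = noiseless_acquisition["cest"]
        roi = ph.label_image == 2
        pos, curve = mtr_asymmetry_curve(cest, roi)
        gmap = compute_glucest_map(cest)
        vals = gmap.values[roi & gmap.valid]
        i3 = np.argmin(np.abs(pos - 3.0))
        assert abs(curve[i3] * 100.0 - vals.mean()) < 1e-9

    def test_peak_near_labeling_offset_slow_exchange(self, schedule):
        """In the slow-exchange regime the asymmetry peaks at the pool's
        resonance (+3 ppm).  (At the fast default exchange rate the
        apparent peak coalesces toward water — checked separately.)"""
        from glucest.bloch import PoolParameters
        slow = PoolParameters(3.0, 900.0, 2e-3, 1.0, 0.01)
        z = simulate_zspectrum([slow], WATER_POOL, schedule)
        series = _single_voxel_series(z, schedule.cest_offsets)
        pos, curve = mtr_asymmetry_curve(series, np.ones((1, 1), bool))
        peak = pos[np.nanargmax(curve)]
        assert abs(peak - 3.0) <= 0.5

    def test_default_pool_contrast_broad_and_positive(
            self, schedule, calibrated_fractions):
        pool = GLU_AMINE_POOL.with_fraction(
            calibrated_fractions["hippo_5.02"])
        z = simulate_zspectrum([pool], WATER_POOL, schedule)
        series = _single_voxel_series(z, schedule.cest_offsets)
        pos, curve = mtr_asymmetry_curve(series, np.ones((1, 1), bool))
        assert np.all(curve > 0)
        assert 0.5 <= pos[np.nanargmax(curve)] <= 3.5

    def test_empty_roi_raises(self, schedule):
        z = simulate_zspectrum([], WATER_POOL, schedule)
        series = _single_voxel_series(z, schedule.cest_offsets)
        with pytest.raises(ValueError, match="ROI"):
            mtr_asymmetry_curve(series, np.zeros((1, 1), bool))


def test_invalid_field_voxels_propagate(noiseless_acquisition):
    """A voxel invalid in the field maps must be invalid (not silently
    filled) in the GluCEST map."""
    ph = noiseless_acquisition["phantom"]
    cest = noiseless_acquisition["cest"]
    b0 = np.zeros(ph.shape)
    b1 = np.ones(ph.shape)
    valid = ph.brain_mask.copy()
    idx = tuple(np.argwhere(ph.label_image == 2)[0])
    valid[idx] = False
    corr = correct_zspectrum(cest, FieldMaps(b0, b1, valid))
    g = compute_glucest_map(corr)
    assert not g.valid[idx]
    assert np.isnan(g.values[idx])
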