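"""Mono-exponential T2 fitting: exactness, degeneracy contracts, bias."""

import numpy as np
import pytest

from nfmri.io import GeometryError, ImageSeries
from nfmri.phantom import DEFAULT_ECHO_TIMES_MS, render_t2_series
from nfmri.t2map import (FLAG_CAPPED, FLAG_FAIL, FLAG_OK, FLAG_OUTSIDE,
                         T2_CAP_MS, compute_t2_map, fit_monoexp, region_t2)

TE8 = np.array(DEFAULT_ECHO_TIMES_MS)


class TestFitMonoexp:
    def test_noiseless_recovery_is_exact(self):
        si = 1000.0 * np.exp(-TE8 / 57.0)
        fit = fit_monoexp(si, TE8)
        assert fit.flag == FLAG_OK
        assert fit.si0 == pytest.approx(1000.0, abs=1e-6)
        assert fit.t2_ms == pytest.approx(57.0, abs=1e-6)

    def test_two_point_closed_form(self):
        # exact data at three echoes; closed form from the outer two
        si0, t2 = 880.0, 43.0
        te = np.array([12.0, 58.5, 105.0])
        si = si0 * np.exp(-te / t2)
        expected_t2 = (105.0 - 12.0) / np.log(si[0] / si[2])
        fit = fit_monoexp(si, te)
        assert fit.t2_ms == pytest.approx(expected_t2, rel=1e-9)
        assert fit.t2_ms == pytest.approx(t2, rel=1e-9)

    def test_constant_signal_is_flagged_never_silent(self):
        fit = fit_monoexp(np.full(8, 500.0), TE8)
        assert fit.flag in (FLAG_FAIL, FLAG_CAPPED)
        if fit.flag == FLAG_CAPPED:
            assert fit.t2_ms <= T2_CAP_MS

    def test_all_zero_signal_flags_fail(self):
        fit = fit_monoexp(np.zeros(8), TE8)
        assert fit.flag == FLAG_FAIL
        assert np.isnan(fit.t2_ms)

    def test_too_few_echoes_is_input_error(self):
        with pytest.raises(ValueError, match="3 echoes"):
            fit_monoexp([10.0, 5.0], [12.0, 20.0])

    def test_duplicate_echo_times_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_monoexp([10.0, 5.0, 2.0], [12.0, 12.0, 30.0])

    def test_echo_permutation_leaves_fit_unchanged(self):
        rng = np.random.default_rng(11)
        si = 900.0 * np.exp(-TE8 / 70.0) + rng.normal(0, 20, 8)
        ref = fit_monoexp(si, TE8)
        perm = rng.permutation(8)
        alt = fit_monoexp(si[perm], TE8[perm])
        assert alt.t2_ms == pytest.approx(ref.t2_ms, rel=1e-9)
        assert alt.si0 == pytest.approx(ref.si0, rel=1e-9)

    def test_nonlinear_never_worse_than_loglinear_seed(self):
        from nfmri.t2map import _loglinear_init

        rng = np.random.default_rng(5)
        for _ in range(20):
            si = 1000.0 * np.exp(-TE8 / rng.uniform(30, 120)) + rng.normal(0, 40, 8)
            if (si > 0).sum() < 3:
                continue
            fit = fit_monoexp(si, TE8)
            si0_0, t2_0 = _loglinear_init(si, TE8)
            sse_init = ((si0_0 * np.exp(-TE8 / t2_0) - si) ** 2).sum()
            sse_fit = fit.residual ** 2
            assert sse_fit <= sse_init + 1e-9


def _series_from(signals, te=TE8):
    """(n_echoes, n_pixels) column signals -> a 1-slice, 1-row series."""
    signals = np.asarray(signals, dtype=float)
    arr = np.zeros((1, len(te), 1, signals.shape[1]))
    arr[0, :, 0, :] = signals
    return ImageSeries(voxels=arr, pixel_spacing_mm=(1.0, 1.0),
                       slice_thickness_mm=10.0, kind="t2-multi-echo",
                       echo_times_ms=tuple(te))


class TestComputeT2Map:
    def test_noiseless_phantom_recovery_exact(self, quiet_truth):
        series = render_t2_series(quiet_truth)
        sub = np.zeros_like(quiet_truth.myocardium_mask)
        sub[0] = quiet_truth.myocardium_mask[0]
        sub[0, ::3] = False  # thin out for speed
        t2map = compute_t2_map(series, sub)
        labels = quiet_truth.class_map()
        for name, code in (("remote", 2), ("enhanced", 3), ("nf", 4)):
            sel = sub & (labels == code)
            if sel.any():
                err = np.abs(t2map.t2_ms[sel] - quiet_truth.regional_t2_ms[name])
                assert err.max() < 1e-6

    def test_masked_out_pixels_untouched(self):
        si = 1000.0 * np.exp(-TE8 / 57.0)
        series = _series_from(np.column_stack([si, si]))
        mask = np.zeros((1, 1, 2), dtype=bool)
        mask[0, 0, 0] = True
        t2map = compute_t2_map(series, mask)
        assert t2map.flags[0, 0, 1] == FLAG_OUTSIDE
        assert np.isnan(t2map.t2_ms[0, 0, 1])
        assert t2map.flags[0, 0, 0] == FLAG_OK

    def test_shape_mismatch_is_geometry_error(self):
        series = _series_from(np.zeros((8, 2)))
        with pytest.raises(GeometryError):
            compute_t2_map(series, np.zeros((2, 5, 5), dtype=bool))

    def test_wrong_kind_rejected(self):
        series = ImageSeries(voxels=np.zeros((1, 4, 4)), pixel_spacing_mm=(1, 1),
                             slice_thickness_mm=10.0, kind="ir-lge", ti_ms=500.0,
                             post_contrast_min=2.0)
        with pytest.raises(ValueError, match="t2-multi-echo"):
            compute_t2_map(series, np.zeros((1, 4, 4), dtype=bool))

    def test_estimator_bias_below_1pct_at_snr20_gaussian(self):
        """Regional-mean bias of the nonlinear estimator, Gaussian noise SNR 20."""
        rng = np.random.default_rng(2024)
        t2_true, si0 = 57.0, 1000.0
        clean = si0 * np.exp(-TE8 / t2_true)
        sigma = clean[0] / 20.0
        vals = []
        for _ in range(100):
            sig = clean[None, :] + rng.normal(0, sigma, (25, 8))
            for row in sig:
                fit = fit_monoexp(row, TE8)
                if fit.flag == FLAG_OK:
                    vals.append(fit.t2_ms)
        bias = abs(np.mean(vals) - t2_true) / t2_true
        assert bias < 0.01


class TestRegionT2:
    def test_uniform_region_has_zero_sd(self):
        si = 1000.0 * np.exp(-TE8 / 57.0)
        series = _series_from(np.column_stack([si, si, si]))
        mask = np.ones((1, 1, 3), dtype=bool)
        t2map = compute_t2_map(series, mask)
        mean, sd, n = region_t2(t2map, mask)
        assert (mean, n) == (pytest.approx(57.0, abs=1e-6), 3)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_two_pixel_sample_sd(self):
        sig = np.column_stack([1000.0 * np.exp(-TE8 / 50.0),
                               1000.0 * np.exp(-TE8 / 70.0)])
        series = _series_from(sig)
        mask = np.ones((1, 1, 2), dtype=bool)
        t2map = compute_t2_map(series, mask)
        mean, sd, n = region_t2(t2map, mask)
        assert mean == pytest.approx(60.0, abs=1e-6)
        assert sd == pytest.approx(14.142135, abs=1e-5)

    def test_empty_region_is_error(self):
        series = _series_from(np.column_stack([1000.0 * np.exp(-TE8 / 50.0)]))
        mask = np.ones((1, 1, 1), dtype=bool)
        t2map = compute_t2_map(series, mask)
        with pytest.raises(ValueError, match="no successfully fitted"):
            region_t2(t2map, np.zeros_like(mask))

    def test_region_outside_mask_rejected(self):
        series = _series_from(np.column_stack([1000.0 * np.exp(-TE8 / 50.0),
                                               1000.0 * np.exp(-TE8 / 50.0)]))
        mask = np.zeros((1, 1, 2), dtype=bool)
        mask[0, 0, 0] = True
        t2map = compute_t2_map(series, mask)
        with pytest.raises(ValueError, match="outside the fitted mask"):
            region_t2(t2map, np.ones_like(mask))
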