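import numpy as np
import pytest
from scipy.stats import pearsonr

from scraman import (
    Spectrum,
    decompose,
    default_axis,
    difference_spectrum,
    fit_baseline_archull,
    fit_baseline_iterpoly,
    simulate_cell,
)
from scraman.decomposition import _lower_convex_hull
from scraman.spectra_io import EXPOSURE_WINDOWS, TimeSeriesSpectra
from scraman.synthetic_data import preset


def _series(axis, frames_intensities, cell_id="c"):
    frames = tuple(
        Spectrum(axis, inten, cell_id=cell_id, exposure_window_s=w)
        for inten, w in zip(frames_intensities, EXPOSURE_WINDOWS)
    )
    return TimeSeriesSpectra(cell_id, frames)


def _lorentz(v, c, a, g):
    return a * (g / 2) ** 2 / ((v - c) ** 2 + (g / 2) ** 2)


class TestDifferenceSpectrum:
    def test_identical_frames_give_zero(self, axis):
        y = np.sin(axis.shifts / 100.0)
        ts = _series(axis, [y, y, y])
        np.testing.assert_array_equal(difference_spectrum(ts).intensities, 0.0)

    def test_closed_form_for_bleaching_fluorescence(self, axis):
        # non-bleaching Raman + fluorescence decaying by factor f per frame:
        # frame0 - frame2 = F0 * (1 - f^2)
        rng = np.random.default_rng(3)
        raman = _lorentz(axis.shifts, 1510.0, 50.0, 16.0)
        f0 = 40.0 * np.exp(-((axis.wavelengths_nm - 700.0) / 40.0) ** 2)
        f = 0.6
        sigma = 0.5
        frames = [
            raman + f0 * f**t + rng.normal(0, sigma, axis.n_pixels) for t in range(3)
        ]
        diff = difference_spectrum(_series(axis, frames))
        expected = f0 * (1.0 - f**2)
        resid = diff.intensities - expected
        assert np.abs(resid.mean()) < 0.1
        assert np.std(resid) == pytest.approx(np.sqrt(2) * sigma, rel=0.15)

    def test_linearity(self, axis):
        rng = np.random.default_rng(4)
        fa = [rng.normal(size=axis.n_pixels) for _ in range(3)]
        fb = [rng.normal(size=axis.n_pixels) for _ in range(3)]
        da = difference_spectrum(_series(axis, fa)).intensities
        db = difference_spectrum(_series(axis, fb)).intensities
        dsum = difference_spectrum(
            _series(axis, [a + b for a, b in zip(fa, fb)])
        ).intensities
        np.testing.assert_allclose(dsum, da + db, atol=1e-12)


class TestIterpolyBaseline:
    def test_exact_low_order_polynomial_reproduced(self):
        ax = default_axis(n_pixels=400)
        x = np.linspace(-1, 1, 400)
        y = 100.0 * (1.0 + 0.8 * x - 0.5 * x**2 + 0.3 * x**5)
        res = fit_baseline_iterpoly(Spectrum(ax, y), presmooth=1)
        assert res.converged
        assert np.max(np.abs(res.baseline - y)) / np.ptp(y) < 1e-6

    def test_recovers_fluorescence_under_peaks(self, axis):
        # order-5 fluorescence + three Lorentzians 10x the curvature scale
        x = np.linspace(-1, 1, axis.n_pixels)
        fluor = 100.0 * (1.5 + x - 0.8 * x**2 + 0.4 * x**3 - 0.3 * x**5)
        amp = 10.0 * np.ptp(fluor) / 10.0 * 10.0  # 10x the baseline variation scale
        peaks = sum(
            _lorentz(axis.shifts, c, amp, 16.0) for c in (1003.0, 1150.0, 1510.0)
        )
        res = fit_baseline_iterpoly(Spectrum(axis, fluor + peaks))
        rmse = np.sqrt(np.mean((res.baseline - fluor) ** 2))
        assert rmse < 0.03 * amp

    def test_baseline_below_smoothed_input_at_convergence(self, axis):
        # on a peak-bearing noiseless input the converged fit must not exceed
        # the (pre-smoothed) input by more than the convergence tolerance
        x = np.linspace(-1, 1, axis.n_pixels)
        fluor = 100.0 * (1.2 - 0.6 * x**2)
        y = fluor + _lorentz(axis.shifts, 1510.0, 80.0, 16.0)
        res = fit_baseline_iterpoly(Spectrum(axis, y))
        from scraman.decomposition import _moving_average

        smoothed = _moving_average(y, 20)
        # small overshoot from polynomial ringing at the truncated peak flanks
        # is tolerated up to 0.5% of the dynamic range
        assert np.all(res.baseline <= smoothed + 0.005 * np.ptp(smoothed))

    def test_constant_offset_equivariance(self, axis):
        rng = np.random.default_rng(9)
        y = _lorentz(axis.shifts, 1500.0, 30.0, 15.0) + rng.normal(0, 1, axis.n_pixels)
        b0 = fit_baseline_iterpoly(Spectrum(axis, y)).baseline
        b1 = fit_baseline_iterpoly(Spectrum(axis, y + 123.0)).baseline
        np.testing.assert_allclose(b1, b0 + 123.0, atol=1e-6)

    def test_too_few_pixels_rejected(self):
        ax = default_axis(n_pixels=10)
        with pytest.raises(ValueError):
            fit_baseline_iterpoly(Spectrum(ax, np.zeros(10)), order=12)


class TestArcHullBaseline:
    def test_straight_line_recovered_between_peaks(self, axis):
        # Gaussian peaks decay to numerically zero away from their centers,
        # so the line must be recovered exactly outside the peak regions
        line = 2.0 + 0.001 * np.arange(axis.n_pixels)
        peaks = 20.0 * np.exp(-0.5 * ((axis.shifts - 1500.0) / 7.0) ** 2)
        peaks += 15.0 * np.exp(-0.5 * ((axis.shifts - 1150.0) / 7.0) ** 2)
        res = fit_baseline_archull(Spectrum(axis, line + peaks))
        away = np.abs(axis.shifts - 1500) > 80
        away &= np.abs(axis.shifts - 1150) > 80
        assert np.max(np.abs(res.baseline[away] - line[away])) < 1e-9

    def test_beats_plain_hull_on_concave_down_hump(self, axis):
        x = np.linspace(0, 1, axis.n_pixels)
        hump = 50.0 * np.sin(np.pi * x) ** 2 + 10.0
        peaks = sum(
            _lorentz(axis.shifts, c, 60.0, 15.0) for c in (1003.0, 1150.0, 1510.0)
        )
        s = Spectrum(axis, hump + peaks)
        arc = fit_baseline_archull(s)
        xpix = np.arange(axis.n_pixels, dtype=float)
        plain = _lower_convex_hull(xpix, s.intensities)
        rmse_arc = np.sqrt(np.mean((arc.baseline - hump) ** 2))
        rmse_plain = np.sqrt(np.mean((plain - hump) ** 2))
        assert rmse_arc < rmse_plain

    def test_never_exceeds_input(self, axis):
        rng = np.random.default_rng(10)
        y = 20 * np.sin(axis.shifts / 400.0) ** 2 + rng.normal(0, 1, axis.n_pixels)
        res = fit_baseline_archull(Spectrum(axis, y))
        assert np.all(res.baseline <= y + 1e-9)


class TestDecompose:
    def test_additivity_exact(self, presets):
        ts, _ = simulate_cell(presets["spheroidene_anaerobe"], seed=12)
        dec = decompose(ts)
        np.testing.assert_array_equal(
            dec.raman.intensities + dec.baseline_first, ts.frames[0].intensities
        )

    def test_zero_fluorescence_gives_near_zero_af(self, axis):
        rng = np.random.default_rng(13)
        sigma = 1.0
        raman = _lorentz(axis.shifts, 1510.0, 50.0, 16.0)
        frames = [raman + rng.normal(0, sigma, axis.n_pixels) for _ in range(3)]
        dec = decompose(_series(axis, frames))
        af_rms = np.sqrt(np.mean(dec.autofluorescence.intensities**2))
        assert af_rms < np.sqrt(2) * sigma  # below the difference-spectrum noise RMS

    def test_af_shape_recovery(self, presets):
        ts, truth = simulate_cell(presets["spirilloxanthin_anaerobe"], seed=14)
        dec = decompose(ts)
        idx = ts.axis.index_window_nm(665.0, 775.0)
        r, _ = pearsonr(dec.autofluorescence.intensities[idx], truth.f0[idx])
        assert r > 0.98

    def test_peak_free_raman_residual_close_to_noise(self, axis):
        rng = np.random.default_rng(15)
        sigma = 1.0
        x = np.linspace(-1, 1, axis.n_pixels)
        fluor = 80.0 * (1 - 0.5 * x**2)
        frames = [
            fluor * np.exp(-0.8 * t) + rng.normal(0, sigma, axis.n_pixels)
            for t in range(3)
        ]
        dec = decompose(_series(axis, frames))
        rms = np.sqrt(np.mean(dec.raman.intensities**2))
        assert rms <= 1.5 * sigma

    def test_unknown_method_rejected(self, presets):
        ts, _ = simulate_cell(presets["nonphototroph"], seed=1)
        with pytest.raises(ValueError):
            decompose(ts, method="magic")
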