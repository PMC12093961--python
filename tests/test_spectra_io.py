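import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scraman import (
    SpectralAxis,
    Spectrum,
    TimeSeriesSpectra,
    calibrate_sensitivity,
    default_axis,
    shift_to_wavelength,
    subtract_background,
    wavelength_to_shift,
)
from scraman.spectra_io import (
    AxisMismatchError,
    CalibrationError,
    EXPOSURE_WINDOWS,
    read_delimited,
    read_frames,
    read_jcamp,
    write_delimited,
    write_frames,
)


class TestAxisConversion:
    @pytest.mark.parametrize(
        "shift,expected,atol",
        [
            (0.0, 632.8, 1e-9),        # zero shift is the excitation line
            (660.0, 661.0, 1.0),       # printed low edge of the window
            (3022.0, 783.0, 1.0),      # printed high edge of the window
        ],
    )
    def test_known_wavelengths(self, shift, expected, atol):
        assert shift_to_wavelength(shift, 632.8) == pytest.approx(expected, abs=atol)

    def test_round_trip_over_full_axis(self, axis):
        back = wavelength_to_shift(axis.wavelengths_nm, axis.excitation_nm)
        assert np.max(np.abs(back - axis.shifts)) < 1e-6

    def test_shift_beyond_excitation_line_rejected(self):
        with pytest.raises(ValueError):
            shift_to_wavelength(1.0e7 / 632.8 + 1, 632.8)

    def test_wavelengths_ascending_and_beyond_excitation(self, axis):
        wl = axis.wavelengths_nm
        assert np.all(np.diff(wl) > 0)
        assert np.all(wl > axis.excitation_nm)


class TestAxisModel:
    def test_silent_region_spans_50_pixels(self, axis):
        # 1,600 pixels uniform in wavelength over the acquisition window put
        # 50 +- 1 pixels into the 2,204-2,274 cm^-1 cell-silent region
        n = axis.index_window(2204.0, 2274.0).size
        assert abs(n - 50) <= 1

    def test_default_axis_shape(self, axis):
        assert axis.n_pixels == 1600
        assert axis.shifts[0] == pytest.approx(660.0)
        assert axis.shifts[-1] == pytest.approx(3022.0)
        # the grid is uniform in wavelength, not in shift
        assert np.allclose(np.diff(axis.wavelengths_nm), np.diff(axis.wavelengths_nm)[0])

    @pytest.mark.parametrize(
        "shifts",
        [[500.0, 400.0, 600.0], [100.0, 100.0, 200.0], [-5.0, 10.0, 20.0], [10.0, 4500.0]],
    )
    def test_invalid_axes_rejected(self, shifts):
        with pytest.raises(ValueError):
            SpectralAxis(np.array(shifts))

    def test_spectrum_length_and_finiteness_enforced(self, axis):
        with pytest.raises(ValueError):
            Spectrum(axis, np.zeros(axis.n_pixels - 1))
        bad = np.zeros(axis.n_pixels)
        bad[3] = np.nan
        with pytest.raises(ValueError):
            Spectrum(axis, bad)

    def test_time_series_validation(self, axis):
        frames = [
            Spectrum(axis, np.zeros(axis.n_pixels), exposure_window_s=w)
            for w in EXPOSURE_WINDOWS
        ]
        ts = TimeSeriesSpectra("c", tuple(frames))
        assert ts.axis == axis
        with pytest.raises(ValueError):
            TimeSeriesSpectra("c", tuple(frames[:2]))
        other = default_axis(n_pixels=800)
        mixed = (
            frames[0],
            frames[1],
            Spectrum(other, np.zeros(800), exposure_window_s=EXPOSURE_WINDOWS[2]),
        )
        with pytest.raises(AxisMismatchError):
            TimeSeriesSpectra("c", mixed)


class TestCalibration:
    def test_flat_response_is_identity(self, make_spectrum):
        raw = make_spectrum(fn=lambda v: np.cos(v / 300.0) + 2.0)
        lamp = make_spectrum(fn=lambda v: np.full_like(v, 3.3))
        out = calibrate_sensitivity(raw, lamp, lamp)
        np.testing.assert_allclose(out.intensities, raw.intensities)
        assert out.calibrated

    def test_half_response_doubles_pixel(self, axis, make_spectrum):
        raw = make_spectrum(np.ones(axis.n_pixels))
        meas = np.ones(axis.n_pixels)
        meas[100] = 0.5
        out = calibrate_sensitivity(raw, make_spectrum(meas), make_spectrum(np.ones(axis.n_pixels)))
        assert out.intensities[100] == pytest.approx(2.0)
        assert out.intensities[101] == pytest.approx(1.0)

    def test_random_response_inverts_forward_simulation(self, axis, make_spectrum):
        rng = np.random.default_rng(11)
        truth = rng.uniform(1.0, 10.0, axis.n_pixels)
        response = rng.uniform(0.2, 5.0, axis.n_pixels)
        reference = rng.uniform(1.0, 2.0, axis.n_pixels)
        raw = make_spectrum(truth * response)
        out = calibrate_sensitivity(
            raw, make_spectrum(response * reference), make_spectrum(reference)
        )
        np.testing.assert_allclose(out.intensities, truth, rtol=1e-9)

    def test_nonpositive_lamp_names_pixel_range(self, axis, make_spectrum):
        lamp = np.ones(axis.n_pixels)
        lamp[200:203] = 0.0
        with pytest.raises(CalibrationError, match="200..202"):
            calibrate_sensitivity(
                make_spectrum(np.ones(axis.n_pixels)),
                make_spectrum(lamp),
                make_spectrum(np.ones(axis.n_pixels)),
            )


class TestBackgroundSubtraction:
    def test_zero_background_is_identity(self, axis, make_spectrum):
        cell = make_spectrum(fn=lambda v: v / 100.0)
        out = subtract_background(cell, [make_spectrum(np.zeros(axis.n_pixels))])
        np.testing.assert_array_equal(out.intensities, cell.intensities)

    def test_cell_equal_to_mean_background_gives_zero(self, axis, make_spectrum):
        b1 = make_spectrum(np.full(axis.n_pixels, 2.0))
        b2 = make_spectrum(np.full(axis.n_pixels, 4.0))
        cell = make_spectrum(np.full(axis.n_pixels, 3.0))
        out = subtract_background(cell, [b1, b2])
        np.testing.assert_allclose(out.intensities, 0.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_subtraction_is_linear(self, seed):
        ax = default_axis(n_pixels=64)
        rng = np.random.default_rng(seed)
        a = Spectrum(ax, rng.normal(size=64))
        b = Spectrum(ax, rng.normal(size=64))
        out = subtract_background(a.with_intensities(a.intensities + b.intensities), [b])
        np.testing.assert_allclose(out.intensities, a.intensities, atol=1e-12)

    def test_axis_mismatch_rejected(self, make_spectrum):
        other = Spectrum(default_axis(n_pixels=100), np.zeros(100))
        with pytest.raises(AxisMismatchError):
            subtract_background(make_spectrum(), [other])

    def test_empty_background_list_rejected(self, make_spectrum):
        with pytest.raises(ValueError):
            subtract_background(make_spectrum(), [])


class TestFileIO:
    def test_delimited_round_trip_bit_identical(self, axis, tmp_path):
        rng = np.random.default_rng(5)
        s = Spectrum(
            axis, rng.normal(size=axis.n_pixels), cell_id="cell_7",
            exposure_window_s=(0.0, 30.0), calibrated=True,
        )
        path = tmp_path / "s.tsv"
        write_delimited(s, path)
        back = read_delimited(path)
        np.testing.assert_array_equal(back.intensities, s.intensities)
        np.testing.assert_array_equal(back.axis.shifts, s.axis.shifts)
        assert back.cell_id == "cell_7"
        assert back.exposure_window_s == (0.0, 30.0)
        assert back.calibrated

    def test_frames_round_trip(self, axis, tmp_path):
        rng = np.random.default_rng(6)
        frames = tuple(
            Spectrum(axis, rng.normal(size=axis.n_pixels), cell_id="c1",
                     exposure_window_s=w)
            for w in EXPOSURE_WINDOWS
        )
        ts = TimeSeriesSpectra("c1", frames)
        path = tmp_path / "ts.tsv"
        write_frames(ts, path)
        back = read_frames(path)
        assert back.cell_id == "c1"
        for f0, f1 in zip(ts.frames, back.frames):
            np.testing.assert_array_equal(f0.intensities, f1.intensities)
            assert f0.exposure_window_s == f1.exposure_window_s

    def test_jcamp_xydata_read(self, tmp_path):
        text = "\n".join([
            "##TITLE=toy carotenoid spectrum",
            "##JCAMP-DX=4.24",
            "##DATA TYPE=RAMAN SPECTRUM",
            "##XUNITS=1/CM",
            "##YUNITS=ARBITRARY",
            "##FIRSTX=1000",
            "##LASTX=1004",
            "##NPOINTS=5",
            "##XFACTOR=1",
            "##YFACTOR=0.5",
            "##XYDATA=(X++(Y..Y))",
            "1000 2 4 6",
            "1003 8 10",
            "##END=",
        ])
        path = tmp_path / "toy.jdx"
        path.write_text(text)
        s = read_jcamp(path)
        np.testing.assert_allclose(s.axis.shifts, [1000, 1001, 1002, 1003, 1004])
        np.testing.assert_allclose(s.intensities, [1, 2, 3, 4, 5])
        assert s.cell_id == "toy carotenoid spectrum"
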