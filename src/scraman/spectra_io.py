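"""Spectral data model, axis conversions, calibration, and file I/O.

The instrument model is a grating spectrograph with a CCD whose pixel grid is
uniform in *wavelength*; Raman shifts are derived per pixel from the
excitation line.  The default axis reproduces a He-Ne (632.8 nm) setup with
1,600 pixels spanning 660-3,022 cm^-1 (~661-783 nm).

All downstream modules consume only :class:`Spectrum` and
:class:`TimeSeriesSpectra`; files on disk are plain delimited text (comment
char ``#``), JCAMP-DX (read-only, AFFN XYDATA), CSV record tables, or JSON
lines logs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralAxis",
    "Spectrum",
    "TimeSeriesSpectra",
    "AxisMismatchError",
    "CalibrationError",
    "shift_to_wavelength",
    "wavelength_to_shift",
    "calibrate_sensitivity",
    "subtract_background",
    "default_axis",
    "read_delimited",
    "write_delimited",
    "read_frames",
    "write_frames",
    "read_jcamp",
    "write_records_csv",
    "append_jsonl",
]

HE_NE_NM = 632.8
DEFAULT_SHIFT_WINDOW = (660.0, 3022.0)
DEFAULT_N_PIXELS = 1600


class AxisMismatchError(ValueError):
    """Two spectra do not share the same spectral axis."""


class CalibrationError(ValueError):
    """Sensitivity calibration is impossible (non-positive lamp response)."""


def shift_to_wavelength(shift: float | np.ndarray, excitation_nm: float = HE_NE_NM):
    """Convert a Raman shift (cm^-1) to the scattered wavelength (nm).

    lambda = 1e7 / (1e7/excitation - shift).  Raises for shifts at or beyond
    the excitation line energy, where the scattered wavenumber would be <= 0.
    """
    nu_exc = 1.0e7 / excitation_nm
    shift = np.asarray(shift, dtype=float)
    if np.any(shift >= nu_exc):
        raise ValueError(
            f"shift must be < excitation wavenumber {nu_exc:.1f} cm^-1"
        )
    out = 1.0e7 / (nu_exc - shift)
    return float(out) if out.ndim == 0 else out


def wavelength_to_shift(wavelength_nm: float | np.ndarray, excitation_nm: float = HE_NE_NM):
    """Inverse of :func:`shift_to_wavelength`."""
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    if np.any(wavelength_nm <= 0):
        raise ValueError("wavelength must be positive")
    out = 1.0e7 / excitation_nm - 1.0e7 / wavelength_nm
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SpectralAxis:
    """Calibrated pixel axis: Raman shifts (cm^-1) plus the excitation line."""

    shifts: np.ndarray
    excitation_nm: float = HE_NE_NM

    def __post_init__(self):
        shifts = np.asarray(self.shifts, dtype=float)
        object.__setattr__(self, "shifts", shifts)
        if shifts.ndim != 1 or shifts.size < 2:
            raise ValueError("axis needs a 1-D array of >= 2 shifts")
        if not np.all(np.isfinite(shifts)):
            raise ValueError("axis shifts must be finite")
        if np.any(np.diff(shifts) <= 0):
            raise ValueError("axis shifts must be strictly ascending")
        if shifts[0] < 0 or shifts[-1] > 4000:
            raise ValueError("axis shifts outside the physical 0-4,000 cm^-1 window")
        if shifts[-1] >= 1.0e7 / self.excitation_nm:
            raise ValueError("axis extends past the excitation line energy")

    @property
    def n_pixels(self) -> int:
        return int(self.shifts.size)

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return shift_to_wavelength(self.shifts, self.excitation_nm)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpectralAxis)
            and self.excitation_nm == other.excitation_nm
            and np.array_equal(self.shifts, other.shifts)
        )

    def __hash__(self):
        return hash((self.excitation_nm, self.shifts.tobytes()))

    def index_window(self, low: float, high: float) -> np.ndarray:
        """Pixel indices with shift in [low, high] (inclusive)."""
        return np.flatnonzero((self.shifts >= low) & (self.shifts <= high))

    def index_window_nm(self, low_nm: float, high_nm: float) -> np.ndarray:
        wl = self.wavelengths_nm
        return np.flatnonzero((wl >= low_nm) & (wl <= high_nm))

    def nearest_pixel(self, shift: float) -> int:
        return int(np.argmin(np.abs(self.shifts - shift)))


def default_axis(
    n_pixels: int = DEFAULT_N_PIXELS,
    shift_window: tuple[float, float] = DEFAULT_SHIFT_WINDOW,
    excitation_nm: float = HE_NE_NM,
) -> SpectralAxis:
    """Instrument axis: pixels uniform in wavelength between the window edges.

    The window is given in Raman shift; the pixel grid is laid out uniformly
    in wavelength (grating + CCD geometry) and each pixel's shift is derived.
    """
    lo_nm = shift_to_wavelength(shift_window[0], excitation_nm)
    hi_nm = shift_to_wavelength(shift_window[1], excitation_nm)
    wl = np.linspace(lo_nm, hi_nm, n_pixels)
    return SpectralAxis(wavelength_to_shift(wl, excitation_nm), excitation_nm)


@dataclass(frozen=True)
class Spectrum:
    """One intensity readout on a calibrated axis, detector units."""

    axis: SpectralAxis
    intensities: np.ndarray
    cell_id: str = ""
    exposure_window_s: tuple[float, float] | None = None
    substrate: str = "optically-trapped"
    calibrated: bool = False
    background_subtracted: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", inten)
        if inten.shape != (self.axis.n_pixels,):
            raise ValueError(
                f"intensities length {inten.size} != axis pixels {self.axis.n_pixels}"
            )
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")

    def with_intensities(self, intensities: np.ndarray, **changes) -> "Spectrum":
        return replace(self, intensities=np.asarray(intensities, dtype=float), **changes)


EXPOSURE_WINDOWS = ((0.0, 30.0), (30.0, 60.0), (60.0, 90.0))


@dataclass(frozen=True)
class TimeSeriesSpectra:
    """Three consecutive 30 s exposures of one cell on a shared axis."""

    cell_id: str
    frames: tuple[Spectrum, Spectrum, Spectrum]

    def __post_init__(self):
        frames = tuple(self.frames)
        object.__setattr__(self, "frames", frames)
        if len(frames) != 3:
            raise ValueError("a time series holds exactly 3 frames")
        ax = frames[0].axis
        for fr in frames[1:]:
            if fr.axis != ax:
                raise AxisMismatchError("frames must share one axis")
        windows = [fr.exposure_window_s for fr in frames]
        if any(w is None for w in windows):
            raise ValueError("every frame needs an exposure window")
        starts = [w[0] for w in windows]
        if sorted(starts) != starts or len(set(starts)) != 3:
            raise ValueError("exposure windows must be strictly increasing")

    @property
    def axis(self) -> SpectralAxis:
        return self.frames[0].axis


def _require_same_axis(*spectra: Spectrum) -> SpectralAxis:
    ax = spectra[0].axis
    for s in spectra[1:]:
        if s.axis != ax:
            raise AxisMismatchError("spectra are on different axes")
    return ax


def calibrate_sensitivity(
    raw: Spectrum, lamp_measured: Spectrum, lamp_reference: Spectrum
) -> Spectrum:
    """Divide out the instrument response measured with a standard lamp.

    corrected = raw / (lamp_measured / lamp_reference), pixelwise.
    """
    _require_same_axis(raw, lamp_measured, lamp_reference)
    bad = (lamp_measured.intensities <= 0) | (lamp_reference.intensities <= 0)
    if np.any(bad):
        idx = np.flatnonzero(bad)
        lo, hi = idx[0], idx[-1]
        raise CalibrationError(
            f"non-positive lamp intensity at pixels {lo}..{hi} "
            f"({raw.axis.shifts[lo]:.1f}-{raw.axis.shifts[hi]:.1f} cm^-1)"
        )
    response = lamp_measured.intensities / lamp_reference.intensities
    return raw.with_intensities(raw.intensities / response, calibrated=True)


def subtract_background(cell: Spectrum, backgrounds: Sequence[Spectrum]) -> Spectrum:
    """Subtract the mean of >=1 background spectra (buffer / substrate).

    Negative residual intensities are preserved; baseline fitting downstream
    tolerates them.
    """
    if len(backgrounds) == 0:
        raise ValueError("need at least one background spectrum")
    _require_same_axis(cell, *backgrounds)
    mean_bg = np.mean([b.intensities for b in backgrounds], axis=0)
    return cell.with_intensities(cell.intensities - mean_bg, background_subtracted=True)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_META_KEYS = ("cell_id", "substrate", "calibrated", "background_subtracted")


def _header_lines(spectrum: Spectrum) -> list[str]:
    lines = [f"# excitation_nm: {spectrum.axis.excitation_nm!r}"]
    if spectrum.cell_id:
        lines.append(f"# cell_id: {spectrum.cell_id}")
    if spectrum.exposure_window_s is not None:
        a, b = spectrum.exposure_window_s
        lines.append(f"# exposure_window_s: {a!r} {b!r}")
    lines.append(f"# substrate: {spectrum.substrate}")
    lines.append(f"# calibrated: {spectrum.calibrated}")
    lines.append(f"# background_subtracted: {spectrum.background_subtracted}")
    return lines


def _parse_header(lines: Iterable[str]) -> dict:
    meta: dict = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" not in body:
            continue
        key, _, val = body.partition(":")
        meta[key.strip()] = val.strip()
    out: dict = {}
    out["excitation_nm"] = float(meta.get("excitation_nm", HE_NE_NM))
    out["cell_id"] = meta.get("cell_id", "")
    if "exposure_window_s" in meta:
        a, b = meta["exposure_window_s"].split()
        out["exposure_window_s"] = (float(a), float(b))
    out["substrate"] = meta.get("substrate", "optically-trapped")
    out["calibrated"] = meta.get("calibrated", "False") == "True"
    out["background_subtracted"] = meta.get("background_subtracted", "False") == "True"
    return out


def write_delimited(spectrum: Spectrum, path: str | Path, delimiter: str = "\t") -> None:
    """Two-column (shift, intensity) text file; metadata in '#' comments.

    Values are written with 17 significant digits so a read-back is
    bit-identical for float64 data.
    """
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(spectrum):
            fh.write(line + "\n")
        for s, i in zip(spectrum.axis.shifts, spectrum.intensities):
            fh.write(f"{s:.17g}{delimiter}{i:.17g}\n")


def read_delimited(path: str | Path, delimiter: str | None = None) -> Spectrum:
    path = Path(path)
    header, rows = [], []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            header.append(line)
        else:
            rows.append(line.split(delimiter))
    meta = _parse_header(header)
    data = np.array(rows, dtype=float)
    axis = SpectralAxis(data[:, 0], excitation_nm=meta.pop("excitation_nm"))
    return Spectrum(axis, data[:, 1], **meta)


def write_frames(ts: TimeSeriesSpectra, path: str | Path, delimiter: str = "\t") -> None:
    """Wide format: shift plus one intensity column per exposure frame."""
    path = Path(path)
    first = ts.frames[0]
    with path.open("w") as fh:
        fh.write(f"# excitation_nm: {ts.axis.excitation_nm!r}\n")
        fh.write(f"# cell_id: {ts.cell_id}\n")
        fh.write(f"# substrate: {first.substrate}\n")
        fh.write(f"# calibrated: {first.calibrated}\n")
        fh.write(f"# background_subtracted: {first.background_subtracted}\n")
        windows = " ".join(
            f"{a!r}-{b!r}" for a, b in (fr.exposure_window_s for fr in ts.frames)
        )
        fh.write(f"# exposure_windows_s: {windows}\n")
        for px in range(ts.axis.n_pixels):
            vals = delimiter.join(f"{fr.intensities[px]:.17g}" for fr in ts.frames)
            fh.write(f"{ts.axis.shifts[px]:.17g}{delimiter}{vals}\n")


def read_frames(path: str | Path, delimiter: str | None = None) -> TimeSeriesSpectra:
    path = Path(path)
    header, rows = [], []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            header.append(line)
        else:
            rows.append(line.split(delimiter))
    meta: dict = {}
    windows = list(EXPOSURE_WINDOWS)
    for line in header:
        body = line.lstrip("#").strip()
        key, _, val = body.partition(":")
        key, val = key.strip(), val.strip()
        if key == "exposure_windows_s":
            windows = []
            for token in val.split():
                a, _, b = token.partition("-")
                windows.append((float(a), float(b)))
        else:
            meta[key] = val
    data = np.array(rows, dtype=float)
    if data.shape[1] != 4:
        raise ValueError("multi-frame file must have shift + 3 intensity columns")
    axis = SpectralAxis(data[:, 0], excitation_nm=float(meta.get("excitation_nm", HE_NE_NM)))
    common = dict(
        cell_id=meta.get("cell_id", ""),
        substrate=meta.get("substrate", "optically-trapped"),
        calibrated=meta.get("calibrated", "False") == "True",
        background_subtracted=meta.get("background_subtracted", "False") == "True",
    )
    frames = tuple(
        Spectrum(axis, data[:, 1 + k], exposure_window_s=windows[k], **common)
        for k in range(3)
    )
    return TimeSeriesSpectra(cell_id=common["cell_id"], frames=frames)


def read_jcamp(path: str | Path, excitation_nm: float = HE_NE_NM) -> Spectrum:
    """Read a single-spectrum JCAMP-DX file (AFFN ``(X++(Y..Y))`` XYDATA).

    Supports the plain numeric dialect: XFACTOR/YFACTOR scaling, one X value
    followed by one or more Y values per data line.  Compressed (SQZ/DIF/DUP)
    ordinate forms are not supported.
    """
    path = Path(path)
    fields: dict[str, str] = {}
    title = ""
    xs: list[float] = []
    ys: list[float] = []
    in_data = False
    deltax: float | None = None
    for raw_line in path.read_text().splitlines():
        line = raw_line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "").lstrip("$")
            val = val.strip()
            if key == "TITLE":
                title = val
            elif key == "XYDATA":
                xf = float(fields.get("XFACTOR", 1.0))
                if "DELTAX" in fields:
                    deltax = float(fields["DELTAX"]) * xf
                elif {"FIRSTX", "LASTX", "NPOINTS"} <= fields.keys():
                    npts = int(float(fields["NPOINTS"]))
                    if npts > 1:
                        deltax = (
                            float(fields["LASTX"]) - float(fields["FIRSTX"])
                        ) / (npts - 1)
                in_data = True
            elif key == "END":
                in_data = False
            else:
                fields[key] = val
                in_data = False
            continue
        if in_data:
            xfactor = float(fields.get("XFACTOR", 1.0))
            yfactor = float(fields.get("YFACTOR", 1.0))
            vals = [float(t) for t in line.replace(",", " ").split()]
            x0 = vals[0] * xfactor
            yvals = [v * yfactor for v in vals[1:]]
            if len(yvals) > 1 and deltax is None:
                raise ValueError(
                    "multi-Y JCAMP lines need DELTAX or FIRSTX/LASTX/NPOINTS"
                )
            step = deltax if deltax is not None else 0.0
            xs.extend(x0 + np.arange(len(yvals)) * step)
            ys.extend(yvals)
    if not xs:
        raise ValueError(f"no XYDATA found in {path}")
    order = np.argsort(xs)
    axis = SpectralAxis(np.asarray(xs)[order], excitation_nm=excitation_nm)
    return Spectrum(axis, np.asarray(ys)[order], cell_id=title)


def write_records_csv(records: pd.DataFrame | Iterable, path: str | Path) -> None:
    """Tabular per-cell record export."""
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.to_dict() if hasattr(r, "to_dict") else r for r in records])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False)


def append_jsonl(record: dict, path: str | Path) -> None:
    """One-record-per-line structured log."""
    with Path(path).open("a") as fh:
        fh.write(json.dumps(record, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
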