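"""Carotenoid peak descriptors: Lorentzian fits, FWHM, SNR, and SNR filters.

The conjugated polyene chain of carotenoids gives two strong
resonance-enhanced stretching bands, nu1 (C=C, ~1,500 cm^-1) and nu2 (C-C,
~1,150 cm^-1).  Each is fitted with a single Lorentzian

    I(v) = A * (G/2)^2 / ((v - v0)^2 + (G/2)^2) + c

where A is the peak height above the constant offset c, v0 the center and G
the full width at half maximum.  The signal-to-noise ratio divides a signal
statistic taken over a few points around the peak by the root mean square of
the intensities in the cell-silent window 2,204-2,274 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
from scipy.optimize import curve_fit

from .spectra_io import Spectrum

__all__ = [
    "PeakFit",
    "SnrResult",
    "NU1_WINDOW",
    "NU2_WINDOW",
    "SILENT_REGION",
    "lorentzian",
    "fit_lorentzian_peak",
    "measure_fwhm",
    "compute_snr",
    "apply_snr_filter",
]

NU1_WINDOW = (1480.0, 1560.0)
NU2_WINDOW = (1110.0, 1180.0)
SILENT_REGION = (2204.0, 2274.0)


@dataclass(frozen=True)
class PeakFit:
    mode: str
    center: float
    amplitude: float
    fwhm: float
    offset: float
    window: tuple[float, float]
    rss: float
    success: bool = True
    message: str = ""

    @property
    def height(self) -> float:
        """Peak intensity at the fitted center (amplitude + offset)."""
        return self.amplitude + self.offset


def lorentzian(v: np.ndarray, center: float, amplitude: float, fwhm: float, offset: float):
    hwhm2 = (fwhm / 2.0) ** 2
    return amplitude * hwhm2 / ((v - center) ** 2 + hwhm2) + offset


def fit_lorentzian_peak(
    s: Spectrum,
    window: tuple[float, float],
    mode: str = "nu1",
    init_fwhm: float = 15.0,
) -> PeakFit:
    """Nonlinear least-squares single-Lorentzian fit inside a shift window.

    Initial center is the argmax in the window; initial width 15 cm^-1.
    A fit is rejected (``success=False``) if the optimizer fails or the
    fitted center is pinned at a window edge.
    """
    idx = s.axis.index_window(*window)
    if idx.size < 8:
        raise ValueError(f"window {window} contains {idx.size} pixels; need >= 8")
    v = s.axis.shifts[idx]
    y = s.intensities[idx]
    c0 = float(np.min(y))
    a0 = max(float(np.max(y) - c0), 1e-12)
    v0 = float(v[np.argmax(y)])
    p0 = (v0, a0, init_fwhm, c0)
    span = v[-1] - v[0]
    bounds = (
        [v[0], 0.0, 0.1, -np.inf],
        [v[-1], np.inf, 10.0 * span, np.inf],
    )
    try:
        popt, _ = curve_fit(lorentzian, v, y, p0=p0, bounds=bounds, maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        return PeakFit(mode, np.nan, np.nan, np.nan, np.nan, window, np.nan,
                       success=False, message=f"optimizer failed: {exc}")
    center, amplitude, fwhm, offset = (float(p) for p in popt)
    rss = float(np.sum((lorentzian(v, *popt) - y) ** 2))
    edge_margin = 0.5 * float(np.median(np.diff(v)))
    if center <= v[0] + edge_margin or center >= v[-1] - edge_margin:
        return PeakFit(mode, center, amplitude, fwhm, offset, window, rss,
                       success=False, message="center pinned at window edge")
    return PeakFit(mode, center, amplitude, fwhm, offset, window, rss)


def measure_fwhm(s: Spectrum, window: tuple[float, float]) -> float:
    """Numeric full width at half maximum inside a window.

    The local baseline is the window minimum; half-maximum crossings on
    either side of the peak are located by linear interpolation.  Useful for
    bands broadened by overlapping carotenoid species, where a single
    Lorentzian understates the width.
    """
    idx = s.axis.index_window(*window)
    if idx.size < 3:
        raise ValueError("window too narrow")
    v = s.axis.shifts[idx]
    y = s.intensities[idx]
    ymin, ymax = float(np.min(y)), float(np.max(y))
    half = (ymin + ymax) / 2.0
    ipk = int(np.argmax(y))

    def _cross(side: slice, reverse: bool) -> float:
        seg_v, seg_y = v[side], y[side]
        if reverse:
            seg_v, seg_y = seg_v[::-1], seg_y[::-1]
        # walk away from the peak until the trace drops through half-max
        for j in range(1, seg_y.size):
            y1, y2 = seg_y[j - 1], seg_y[j]
            if (y1 - half) * (y2 - half) <= 0 and y1 != y2:
                t = (half - y1) / (y2 - y1)
                return float(seg_v[j - 1] + t * (seg_v[j] - seg_v[j - 1]))
        raise ValueError("no half-maximum crossing inside window")

    left = _cross(slice(0, ipk + 1), reverse=True)
    right = _cross(slice(ipk, None), reverse=False)
    return abs(right - left)


@dataclass(frozen=True)
class SnrResult:
    value: float
    signal_stat: str
    n_signal_points: int
    n_used: int
    silent_region: tuple[float, float]
    signal: float
    noise_rms: float


def compute_snr(
    s: Spectrum,
    center: float,
    n_signal_points: int = 5,
    signal_stat: str = "mean",
    silent_region: tuple[float, float] = SILENT_REGION,
) -> SnrResult:
    """SNR of a resonance Raman peak against the silent-region noise floor.

    signal: mean (default) or max of ``n_signal_points`` pixels centered on
    the pixel nearest ``center`` (3-7 points; the max statistic is the
    environmental-sample mode).  noise: RMS of the silent-region intensities.
    """
    if not 3 <= n_signal_points <= 7:
        raise ValueError("n_signal_points must be in 3..7")
    if signal_stat not in ("mean", "max"):
        raise ValueError("signal_stat must be 'mean' or 'max'")
    shifts = s.axis.shifts
    if not (shifts[0] <= center <= shifts[-1]):
        raise ValueError("peak center outside axis")
    silent_idx = s.axis.index_window(*silent_region)
    if silent_idx.size == 0:
        raise ValueError("silent region outside axis")
    noise = float(np.sqrt(np.mean(s.intensities[silent_idx] ** 2)))
    if noise == 0.0:
        raise ValueError("silent-region RMS is zero; SNR undefined")
    ipk = s.axis.nearest_pixel(center)
    half = n_signal_points // 2
    lo = max(0, ipk - half)
    hi = min(shifts.size, ipk + half + 1)
    seg = s.intensities[lo:hi]
    signal = float(np.max(seg) if signal_stat == "max" else np.mean(seg))
    return SnrResult(
        value=signal / noise,
        signal_stat=signal_stat,
        n_signal_points=n_signal_points,
        n_used=int(seg.size),
        silent_region=silent_region,
        signal=signal,
        noise_rms=noise,
    )


def apply_snr_filter(
    records: Iterable,
    threshold: float,
    snr: Callable[[object], float] | None = None,
) -> tuple[list, list[dict]]:
    """Exclude records with SNR strictly below the threshold.

    A record at exactly the threshold is kept (the exclusion rule is
    SNR < threshold).  Returns (kept, rejection log); each log entry records
    the rejected record's SNR and the threshold in force.
    """
    if snr is None:
        snr = lambda r: r.snr_nu1  # noqa: E731 - default accessor
    kept: list = []
    rejected: list[dict] = []
    for rec in records:
        value = float(snr(rec))
        if value < threshold:
            rejected.append({
                "record": rec,
                "snr": value,
                "threshold": threshold,
                "reason": f"SNR {value:.3g} < {threshold}",
            })
        else:
            kept.append(rec)
    return kept, rejected
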