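"""Scalar scores per cell: normalized peak intensities and AF intensity.

Raw detector counts vary with focus, trap position and cell size, so every
score is divided by a per-cell internal standard: the Euclidean norm of the
C-H stretching region of the *last* frame of the series (by the third frame
the bleachable signal is largely gone, leaving the non-resonant biomass
bands).  The region is Savitzky-Golay smoothed (15 points, order 2) before
taking the norm.  A global detector gain therefore cancels out of every
score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .peak_analysis import PeakFit, NU1_WINDOW
from .spectra_io import Spectrum

__all__ = [
    "CellRecord",
    "CH_REGION",
    "AF_WINDOW_NM",
    "ch_norm",
    "normalized_peak_intensity",
    "species_average_spectrum",
    "af_intensity",
    "af_threshold",
    "flag_af_positive",
]

CH_REGION = (2800.0, 3022.0)
AF_WINDOW_NM = (737.0, 776.0)
AF_SHAPE_WINDOW_NM = (665.0, 775.0)


@dataclass
class CellRecord:
    """Per-cell descriptor row produced by the pipeline."""

    cell_id: str
    group: str = ""
    nu1_center: float = np.nan
    nu2_center: float = np.nan
    snr_nu1: float = np.nan
    snr_nu2: float = np.nan
    nu1_intensity: float = np.nan
    nu2_intensity: float = np.nan
    af_intensity: float = np.nan
    carotenoid_positive: bool = False
    af_positive: bool = False
    af_spectrum: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("af_spectrum")
        return d


def ch_norm(
    last_frame: Spectrum,
    region: tuple[float, float] = CH_REGION,
    sg_window: int = 15,
    sg_order: int = 2,
) -> float:
    """Vector norm of the smoothed C-H stretching region of the last frame."""
    smoothed = savgol_filter(last_frame.intensities, sg_window, sg_order)
    idx = last_frame.axis.index_window(*region)
    if idx.size < 2:
        raise ValueError(f"C-H region {region} holds only {idx.size} pixels")
    seg = smoothed[idx]
    norm = float(np.linalg.norm(seg))
    if norm == 0.0:
        raise ValueError("C-H region is all zero; normalization impossible")
    return norm


def _mean_around(s: Spectrum, center: float, n_points: int) -> float:
    ipk = s.axis.nearest_pixel(center)
    half = n_points // 2
    lo = max(0, ipk - half)
    hi = min(s.axis.n_pixels, ipk + half + 1)
    return float(np.mean(s.intensities[lo:hi]))


def normalized_peak_intensity(
    raman: Spectrum, fit: PeakFit, ch: float, n_points: int = 5
) -> float:
    """Mean of a few points around the fitted peak center, over the C-H norm."""
    if ch <= 0:
        raise ValueError("C-H norm must be positive")
    if not 3 <= n_points <= 7:
        raise ValueError("n_points must be in 3..7")
    return _mean_around(raman, fit.center, n_points) / ch


def species_average_spectrum(
    raman_spectra: Sequence[Spectrum],
    fits: Sequence[PeakFit] | None = None,
    nu1_window: tuple[float, float] = NU1_WINDOW,
) -> tuple[Spectrum, list[dict]]:
    """Average of Raman components after nu1-normalizing each cell.

    Each spectrum is divided by its nu1 peak intensity (fitted height when a
    fit is supplied, otherwise the raw window maximum) and the normalized
    spectra are averaged pixelwise; the result's nu1 intensity is ~1.
    Spectra with non-positive nu1 intensity are excluded and logged.
    """
    if len(raman_spectra) == 0:
        raise ValueError("need at least one spectrum")
    kept = []
    log: list[dict] = []
    for i, s in enumerate(raman_spectra):
        if fits is not None:
            peak = fits[i].height
        else:
            idx = s.axis.index_window(*nu1_window)
            peak = float(np.max(s.intensities[idx]))
        if not np.isfinite(peak) or peak <= 0:
            log.append({"index": i, "cell_id": s.cell_id,
                        "reason": f"non-positive nu1 intensity {peak!r}"})
            continue
        kept.append(s.intensities / peak)
    if not kept:
        raise ValueError("no spectrum with positive nu1 intensity")
    ref = raman_spectra[0]
    return ref.with_intensities(np.mean(kept, axis=0), cell_id="average"), log


def af_intensity(
    af: Spectrum, ch: float, window_nm: tuple[float, float] = AF_WINDOW_NM
) -> float:
    """Maximum of the autofluorescence component in 737-776 nm over the C-H norm."""
    if ch <= 0:
        raise ValueError("C-H norm must be positive")
    idx = af.axis.index_window_nm(*window_nm)
    if idx.size == 0:
        raise ValueError(f"window {window_nm} nm outside axis")
    return float(np.max(af.intensities[idx])) / ch


def af_threshold(control_intensities: Sequence[float]) -> float:
    """AF-positivity threshold: the highest AF intensity among control cells.

    Modeled on a nonphototrophic control population (n=25); the defining
    control cell is itself negative because the positivity rule is a strict
    inequality.
    """
    vals = np.asarray(list(control_intensities), dtype=float)
    if vals.size == 0:
        raise ValueError("control set is empty")
    return float(np.max(vals))


def flag_af_positive(intensity: float, threshold: float) -> bool:
    """Strict > rule: a cell exactly at the control maximum is negative."""
    return bool(intensity > threshold)
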