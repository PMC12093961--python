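"""Synthetic single-cell spectra with known ground truth.

The measurement model mirrors the instrument geometry (1,600 pixels uniform
in wavelength over 660-3,022 cm^-1 at 632.8 nm excitation) and the
photophysics the analysis assumes: per frame t in {0, 1, 2}

    I_t = R0 * exp(-k_R t) + F0 * exp(-k_F t) + B + eps,   eps ~ N(0, sigma^2)

where R0 is the resonance-Raman component (Lorentzians in shift space at the
carotenoid nu1/nu2/nu3 positions), F0 the autofluorescence component (broad
Gaussian bands defined in *wavelength* space, optionally with a monotone
rise toward 780 nm as seen for bacteriochlorophyll-a-type emission), and B a
non-bleaching background holding the offset and the C-H stretching band of
the biomass.  Fluorescence bleaches at least as fast as the Raman signal in
the default scenarios (k_F >= k_R).

Populations draw per-cell profiles from mixture weights and jitter the
component amplitudes with lognormal between-cell variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra_io import (
    EXPOSURE_WINDOWS,
    SpectralAxis,
    Spectrum,
    TimeSeriesSpectra,
    default_axis,
)

__all__ = [
    "SpeciesProfile",
    "SimGroundTruth",
    "PopulationSample",
    "simulate_cell",
    "simulate_population",
    "preset_profiles",
    "DEFAULT_BLEACH",
    "DEFAULT_NOISE_SIGMA",
]

# default study conditions: fluorescence bleaches fast (most of it is gone
# by the third frame), carotenoid resonance Raman bleaches slowly, and the
# detector noise floor is one count RMS
DEFAULT_BLEACH = (0.8, 0.05)
DEFAULT_NOISE_SIGMA = 1.0
DEFAULT_BACKGROUND = 5.0
DEFAULT_CV = 0.25


@dataclass(frozen=True)
class SpeciesProfile:
    """Spectral fingerprint of one (possibly hypothetical) species.

    Raman bands are (center cm^-1, amplitude, fwhm cm^-1); autofluorescence
    bands are (center nm, fwhm nm, weight) plus an optional sigmoidal rise
    toward 780 nm.  ``conjugation_n`` is annotation only.
    """

    name: str
    nu1_center: float
    nu2_center: float
    nu3_center: float = 1003.0
    nu1_amplitude: float = 60.0
    nu2_amplitude: float = 45.0
    nu3_amplitude: float = 20.0
    nu1_fwhm: float = 16.0
    nu2_fwhm: float = 14.0
    nu3_fwhm: float = 12.0
    af_bands: tuple[tuple[float, float, float], ...] = ()
    af_rise_weight: float = 0.0
    af_amplitude: float = 40.0
    ch_amplitude: float = 30.0
    conjugation_n: int | None = None

    def has_carotenoid(self) -> bool:
        return self.nu1_amplitude > 0 or self.nu2_amplitude > 0

    def has_af(self) -> bool:
        return self.af_amplitude > 0 and (bool(self.af_bands) or self.af_rise_weight > 0)


@dataclass(frozen=True)
class SimGroundTruth:
    cell_id: str
    profile: SpeciesProfile
    f0: np.ndarray
    r0: np.ndarray
    background: np.ndarray
    k_f: float
    k_r: float
    noise_sigma: float
    amplitude_scale: float = 1.0


@dataclass(frozen=True)
class PopulationSample:
    cells: list[TimeSeriesSpectra]
    truths: list[SimGroundTruth]
    labels: list[str]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for t, lab in zip(self.truths, self.labels):
            rows.append({
                "cell_id": t.cell_id,
                "label": lab,
                "nu1_center": t.profile.nu1_center,
                "nu2_center": t.profile.nu2_center,
                "nu1_amplitude": t.profile.nu1_amplitude * t.amplitude_scale,
                "af_amplitude": t.profile.af_amplitude * t.amplitude_scale,
                "k_f": t.k_f,
                "k_r": t.k_r,
                "noise_sigma": t.noise_sigma,
            })
        return pd.DataFrame(rows)


def _lorentz(x: np.ndarray, center: float, amplitude: float, fwhm: float) -> np.ndarray:
    h2 = (fwhm / 2.0) ** 2
    return amplitude * h2 / ((x - center) ** 2 + h2)


def _gauss(x: np.ndarray, center: float, fwhm: float, weight: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return weight * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def raman_component(profile: SpeciesProfile, axis: SpectralAxis) -> np.ndarray:
    v = axis.shifts
    out = np.zeros_like(v)
    for c, a, w in (
        (profile.nu1_center, profile.nu1_amplitude, profile.nu1_fwhm),
        (profile.nu2_center, profile.nu2_amplitude, profile.nu2_fwhm),
        (profile.nu3_center, profile.nu3_amplitude, profile.nu3_fwhm),
    ):
        if a > 0:
            out += _lorentz(v, c, a, w)
    return out


def af_component(profile: SpeciesProfile, axis: SpectralAxis) -> np.ndarray:
    """Fluorescence shape evaluated in wavelength space, then sampled per pixel."""
    wl = axis.wavelengths_nm
    shape = np.zeros_like(wl)
    for center_nm, fwhm_nm, weight in profile.af_bands:
        shape += _gauss(wl, center_nm, fwhm_nm, weight)
    if profile.af_rise_weight > 0:
        shape += profile.af_rise_weight / (1.0 + np.exp(-(wl - 765.0) / 10.0))
    return profile.af_amplitude * shape


def background_component(
    profile: SpeciesProfile, axis: SpectralAxis, level: float = DEFAULT_BACKGROUND
) -> np.ndarray:
    """Non-bleaching part: constant offset + the C-H stretching band (~2,930)."""
    return level + _lorentz(axis.shifts, 2930.0, profile.ch_amplitude, 65.0)


def simulate_cell(
    profile: SpeciesProfile,
    bleach: tuple[float, float] = DEFAULT_BLEACH,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int | np.random.Generator = 0,
    axis: SpectralAxis | None = None,
    cell_id: str = "cell_0",
    amplitude_scale: float = 1.0,
    background_level: float = DEFAULT_BACKGROUND,
    poisson: bool = False,
) -> tuple[TimeSeriesSpectra, SimGroundTruth]:
    """Three consecutive frames of one cell, plus the generating truth.

    ``bleach = (k_F, k_R)`` are per-frame exponential decay constants.
    ``poisson=True`` replaces additive Gaussian noise with Poisson counting
    noise around the noiseless frame (floored at zero intensity).
    """
    if noise_sigma <= 0:
        raise ValueError("noise_sigma must be > 0")
    k_f, k_r = bleach
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if axis is None:
        axis = default_axis()
    r0 = amplitude_scale * raman_component(profile, axis)
    f0 = amplitude_scale * af_component(profile, axis)
    bg = background_component(profile, axis, level=background_level)
    frames = []
    for t, window in enumerate(EXPOSURE_WINDOWS):
        clean = r0 * np.exp(-k_r * t) + f0 * np.exp(-k_f * t) + bg
        if poisson:
            noisy = rng.poisson(np.clip(clean, 0.0, None)).astype(float)
        else:
            noisy = clean + rng.normal(0.0, noise_sigma, size=axis.n_pixels)
        frames.append(Spectrum(
            axis, noisy, cell_id=cell_id, exposure_window_s=window,
            calibrated=True, background_subtracted=False,
        ))
    ts = TimeSeriesSpectra(cell_id=cell_id, frames=tuple(frames))
    truth = SimGroundTruth(
        cell_id=cell_id, profile=profile, f0=f0, r0=r0, background=bg,
        k_f=k_f, k_r=k_r, noise_sigma=noise_sigma, amplitude_scale=amplitude_scale,
    )
    return ts, truth


def simulate_population(
    profiles: list[SpeciesProfile],
    weights: list[float] | None = None,
    n_cells: int = 25,
    cv: float = DEFAULT_CV,
    bleach: tuple[float, float] = DEFAULT_BLEACH,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
    axis: SpectralAxis | None = None,
    poisson: bool = False,
) -> PopulationSample:
    """Mixture population with lognormal between-cell amplitude variability.

    Each cell draws its profile by the mixture weights and a lognormal
    amplitude factor with coefficient of variation ``cv`` (cv=0 disables the
    jitter); noise is independent per cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if weights is None:
        weights = [1.0 / len(profiles)] * len(profiles)
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(profiles) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must match profiles and sum to 1")
    rng = np.random.default_rng(seed)
    if axis is None:
        axis = default_axis()
    if cv > 0:
        log_sigma = np.sqrt(np.log(1.0 + cv**2))
    cells, truths, labels = [], [], []
    for i in range(n_cells):
        pick = int(rng.choice(len(profiles), p=weights))
        profile = profiles[pick]
        scale = 1.0
        if cv > 0:
            scale = float(rng.lognormal(mean=-0.5 * log_sigma**2, sigma=log_sigma))
        ts, truth = simulate_cell(
            profile, bleach=bleach, noise_sigma=noise_sigma, seed=rng,
            axis=axis, cell_id=f"cell_{i:04d}", amplitude_scale=scale,
            poisson=poisson,
        )
        cells.append(ts)
        truths.append(truth)
        labels.append(profile.name)
    return PopulationSample(cells=cells, truths=truths, labels=labels)


# Autofluorescence shape families used below:
#   bchl-a-like  : 690 nm band, ~760 nm shoulder, rise toward 780 nm
#   bchl-b-like  : 690 nm band, slight 740 nm bulge, no long-wavelength rise
#   730-peaked   : single broad band near 730 nm (environmental shape)
_BCHL_A_BANDS = ((690.0, 30.0, 1.0), (758.0, 22.0, 0.45))
_BCHL_B_BANDS = ((690.0, 30.0, 1.0), (740.0, 25.0, 0.2))
_METHYLO_BANDS = ((680.0, 26.0, 1.0), (760.0, 24.0, 0.8))
_ENV730_BANDS = ((730.0, 40.0, 1.0),)


def preset_profiles() -> list[SpeciesProfile]:
    """Named species fingerprints spanning nu1 1,503-1,531 cm^-1.

    Carotenoid positions follow reported band positions for the respective
    pigment classes (spirilloxanthin ~1,505, spheroidene ~1,519,
    beta-carotene-like ~1,523, flexirubin 1,531/1,133, pink
    Methylobacterium-like isolate 1,507/1,152); the three autofluorescence
    shape families mimic bacteriochlorophyll-a, bacteriochlorophyll-b and a
    730 nm-peaked environmental emission.
    """
    return [
        SpeciesProfile(
            name="spirilloxanthin_anaerobe", nu1_center=1505.0, nu2_center=1150.0,
            af_bands=_BCHL_A_BANDS, af_rise_weight=0.9, af_amplitude=40.0,
            conjugation_n=13,
        ),
        SpeciesProfile(
            name="spheroidene_anaerobe", nu1_center=1519.0, nu2_center=1156.0,
            af_bands=_BCHL_A_BANDS, af_rise_weight=1.0, af_amplitude=40.0,
            conjugation_n=10,
        ),
        SpeciesProfile(
            name="bchl_b_anaerobe", nu1_center=1528.0, nu2_center=1155.0,
            af_bands=_BCHL_B_BANDS, af_rise_weight=0.0, af_amplitude=40.0,
            conjugation_n=9,
        ),
        SpeciesProfile(
            name="methylobacterium_like", nu1_center=1507.0, nu2_center=1152.0,
            af_bands=_METHYLO_BANDS, af_rise_weight=0.6, af_amplitude=25.0,
            conjugation_n=11,
        ),
        SpeciesProfile(
            name="env_long_chain", nu1_center=1503.0, nu2_center=1149.0,
            af_bands=_ENV730_BANDS, af_rise_weight=0.0, af_amplitude=25.0,
            conjugation_n=13,
        ),
        SpeciesProfile(
            name="beta_carotene_like", nu1_center=1523.0, nu2_center=1157.0,
            af_bands=(), af_rise_weight=0.0, af_amplitude=0.0,
            conjugation_n=11,
        ),
        SpeciesProfile(
            name="flexirubin_like", nu1_center=1531.0, nu2_center=1133.0,
            af_bands=(), af_rise_weight=0.0, af_amplitude=0.0,
        ),
        SpeciesProfile(
            name="nonphototroph", nu1_center=1510.0, nu2_center=1152.0,
            nu1_amplitude=0.0, nu2_amplitude=0.0, nu3_amplitude=0.0,
            af_bands=(), af_rise_weight=0.0, af_amplitude=0.0,
        ),
    ]


def preset(name: str) -> SpeciesProfile:
    for p in preset_profiles():
        if p.name == name:
            return p
    raise KeyError(f"no preset named {name!r}")
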