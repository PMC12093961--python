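"""Unmixing of autofluorescence and resonance-Raman components.

Pigmented cells excited near an electronic absorption emit both a broad
autofluorescence continuum and resonance-enhanced Raman bands; both
photobleach under continued illumination, the fluorescence typically faster.
Subtracting the last 30 s frame from the first isolates the bleachable part
of the signal; the *baseline* of that difference spectrum is taken as the
autofluorescence component, while the Raman component is the first frame
minus its own fitted baseline.  By construction

    raman + baseline_first == frame_0          (pixelwise, machine precision)

Two baseline estimators are provided:

``iterpoly``
    Iterative least-squares polynomial (modified polyfit): presmooth with a
    moving average, fit a polynomial over the whole axis, clip the fit to the
    working spectrum from above (pointwise minimum), feed the clipped curve
    back in, and iterate.  Peaks are progressively truncated so the
    polynomial relaxes onto the fluorescence continuum.

``archull``
    Arc-corrected lower convex hull for baselines too curved for a
    polynomial: subtract a circular arc capturing the gross curvature, take
    the lower convex hull of the residual, add the arc back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .spectra_io import Spectrum, TimeSeriesSpectra

__all__ = [
    "BaselineResult",
    "DecompositionResult",
    "difference_spectrum",
    "fit_baseline_iterpoly",
    "fit_baseline_archull",
    "fit_baseline",
    "decompose",
]


@dataclass(frozen=True)
class BaselineResult:
    baseline: np.ndarray
    method: str
    iterations: int
    converged: bool
    params: dict


@dataclass(frozen=True)
class DecompositionResult:
    """Two-component split of one cell's time series."""

    autofluorescence: Spectrum
    raman: Spectrum
    baseline_first: np.ndarray
    difference: Spectrum
    baseline_results: dict


def difference_spectrum(ts: TimeSeriesSpectra) -> Spectrum:
    """First frame minus last frame: the photobleached signal fraction."""
    first, last = ts.frames[0], ts.frames[2]
    return first.with_intensities(first.intensities - last.intensities)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float, copy=True)
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def fit_baseline_iterpoly(
    s: Spectrum,
    order: int = 12,
    presmooth: int = 20,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> BaselineResult:
    """Iterative polynomial baseline (modified-polyfit family).

    Parameters mirror the published protocol: polynomial order 12 and a
    presmoothing factor of 20 (read as a 20-point moving-average window
    applied once, before the first iteration).  Convergence is declared when
    the working spectrum changes by less than ``tol`` times the input
    dynamic range; the final *fitted polynomial* is returned as the
    baseline.
    """
    y = np.asarray(s.intensities, dtype=float)
    if y.size < order + 1:
        raise ValueError(f"need at least order+1={order + 1} pixels, got {y.size}")
    work = _moving_average(y, presmooth)
    scale = float(np.ptp(work))
    # least-squares polynomial projection, precomputed once: pixel coordinate
    # mapped to [-1, 1] keeps the order-12 Vandermonde conditioned, and the
    # orthonormal basis Q makes each iteration a cheap matrix product
    x = np.linspace(-1.0, 1.0, y.size)
    q, _ = np.linalg.qr(np.polynomial.polynomial.polyvander(x, order))
    fit_vals = work.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        fit_vals = q @ (q.T @ work)
        new_work = np.minimum(fit_vals, work)
        delta = float(np.max(np.abs(new_work - work)))
        work = new_work
        if delta <= tol * scale:
            converged = True
            break
    return BaselineResult(
        baseline=fit_vals,
        method="iterpoly",
        iterations=iterations,
        converged=converged,
        params={"order": order, "presmooth": presmooth, "max_iter": max_iter, "tol": tol},
    )


def _lower_convex_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Piecewise-linear lower convex hull evaluated at every x (rubber band)."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # pop i2 if it lies on or above the segment i1 -> i
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (x[i] - x[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(x, x[hull], y[hull])


def _circle_through(p1, p2, p3):
    (x1, y1), (x2, y2), (x3, y3) = p1, p2, p3
    d = 2.0 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    if abs(d) < 1e-12:
        return None
    s1, s2, s3 = x1**2 + y1**2, x2**2 + y2**2, x3**2 + y3**2
    ux = (s1 * (y2 - y3) + s2 * (y3 - y1) + s3 * (y1 - y2)) / d
    uy = (s1 * (x3 - x2) + s2 * (x1 - x3) + s3 * (x2 - x1)) / d
    r2 = (x1 - ux) ** 2 + (y1 - uy) ** 2
    return ux, uy, r2


def fit_baseline_archull(s: Spectrum, median_window: int | None = None) -> BaselineResult:
    """Arc-corrected lower convex hull baseline.

    A plain lower convex hull cannot follow a concave-down (dome-shaped)
    fluorescence continuum: it short-circuits the dome with the endpoint
    chord.  The arc correction estimates the gross curvature with a circular
    arc through the two endpoints and the interior point of a median-filtered
    copy farthest from the endpoint chord, subtracts the arc, hulls the
    residual, and adds the arc back.  Degenerate geometry (collinear points,
    arc not single-valued in x) falls back to the plain lower convex hull.
    The result never exceeds the input at any pixel.
    """
    y = np.asarray(s.intensities, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 pixels")
    x = np.arange(n, dtype=float)
    yrange = float(np.ptp(y))
    if yrange == 0.0:
        return BaselineResult(y.copy(), "archull", 1, True, {"degenerate": True})
    if median_window is None:
        median_window = max(5, n // 8)
    if median_window % 2 == 0:
        median_window += 1
    ys = median_filter(y, size=min(median_window, n), mode="nearest")

    # scaled coordinates keep the circle geometry unit-free
    xs = x / (n - 1)
    ysc = (ys - y.min()) / yrange
    chord = ysc[0] + (ysc[-1] - ysc[0]) * xs
    dev = ysc - chord
    interior = slice(1, n - 1)
    i_far = 1 + int(np.argmax(np.abs(dev[interior])))
    arc_scaled = None
    yscale = 1.0
    # deviations under 2% of the dynamic range are treated as a straight
    # baseline (the plain hull is then exact); larger ones get the arc
    if abs(dev[i_far]) > 0.02:
        # the y-unit of the arc construction is arbitrary; shrink it when the
        # apex deviation approaches half the chord so the arc stays a
        # single-valued function of x
        if abs(dev[i_far]) > 0.35:
            yscale = 0.35 / abs(dev[i_far])
        ya = ysc * yscale
        circ = _circle_through((xs[0], ya[0]), (xs[i_far], ya[i_far]), (xs[-1], ya[-1]))
        if circ is not None:
            ux, uy, r2 = circ
            signs = np.sign([ya[0] - uy, ya[i_far] - uy, ya[-1] - uy])
            if signs[0] != 0 and np.all(signs == signs[0]):
                disc = r2 - (xs - ux) ** 2
                if np.all(disc >= -1e-12):
                    arc_scaled = (
                        uy + signs[0] * np.sqrt(np.clip(disc, 0.0, None))
                    ) / yscale
    if arc_scaled is None:
        baseline = _lower_convex_hull(x, y)
        return BaselineResult(
            baseline, "archull", 1, True,
            {"median_window": median_window, "fallback": "plain-hull"},
        )
    arc = arc_scaled * yrange + y.min()
    residual = y - arc
    baseline = _lower_convex_hull(x, residual) + arc
    return BaselineResult(
        baseline, "archull", 1, True, {"median_window": median_window, "fallback": None}
    )


def fit_baseline(s: Spectrum, method: str = "iterpoly", **params) -> BaselineResult:
    if method == "iterpoly":
        return fit_baseline_iterpoly(s, **params)
    if method == "archull":
        return fit_baseline_archull(s, **params)
    raise ValueError(f"unknown baseline method: {method!r}")


def decompose(ts: TimeSeriesSpectra, method: str = "iterpoly", **params) -> DecompositionResult:
    """Split a 3-frame series into autofluorescence and Raman components.

    autofluorescence = baseline(frame_0 - frame_2)
    raman            = frame_0 - baseline(frame_0)

    The two baselines are fitted independently with the chosen method.
    """
    diff = difference_spectrum(ts)
    af_fit = fit_baseline(diff, method=method, **params)
    first = ts.frames[0]
    first_fit = fit_baseline(first, method=method, **params)
    raman = first.with_intensities(first.intensities - first_fit.baseline)
    af = diff.with_intensities(af_fit.baseline)
    return DecompositionResult(
        autofluorescence=af,
        raman=raman,
        baseline_first=first_fit.baseline,
        difference=diff,
        baseline_results={"difference": af_fit, "first": first_fit},
    )
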