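# Methods

This note documents the models, conventions and design choices behind
`scraman`, in the spirit of a methods appendix: what is computed, under
which assumptions, with which defaults, and what the synthetic tests do and
do not demonstrate.

## Instrument and axis model

The axis model is a grating spectrograph with a 1,600-pixel CCD. The pixel
grid is taken to be **uniform in wavelength**, not in wavenumber, spanning
the Raman-shift window 660–3,022 cm⁻¹ at 632.8 nm (He–Ne) excitation
(≈ 660.4–782.4 nm; displayed wavelengths are rounded to the nearest nm,
internal values stay floating). Per-pixel shifts are derived from
λ = 10⁷/(10⁷/λ_exc − ν̃). Two consequences worth knowing:

- the shift spacing varies from ≈ 1.8 cm⁻¹ at the low end to ≈ 1.25 cm⁻¹ at
  the high end of the axis;
- the 2,204–2,274 cm⁻¹ silent region spans exactly 50 pixels on the default
  axis, which fixes the noise-RMS sample size of the SNR statistic.

The uniform-wavelength assumption is a modeling choice: a real instrument
deviates slightly (grating dispersion is not perfectly linear), but nothing
downstream depends on the exact grid beyond monotonicity.

Sensitivity calibration divides by a lamp response (measured ÷ reference,
pixelwise) and refuses non-positive lamp values, naming the offending pixel
range. Background subtraction removes the mean of any number of buffer or
substrate spectra; negative residuals are preserved, never clipped — the
baseline fitters tolerate them.

## Decomposition

The two-component model is: every cell spectrum is autofluorescence +
resonance Raman + non-bleaching background, with the electronically resonant
parts (fluorescence, resonance Raman) photobleaching over the three 30 s
frames. The difference spectrum first-minus-last isolates the bleachable
signal; its *baseline* is the autofluorescence component (the bleached
Raman bands sit on top and are truncated away by the baseline fit). The
Raman component is the first frame minus its own baseline, so

    raman + baseline_first == frame_0   (exact, by construction)

holds to machine precision on any input. The residual
`baseline_first − autofluorescence` is the non-bleaching broad background;
it is recoverable from the parts but deliberately not given its own field,
keeping the two-component framing.

The two baselines (difference spectrum; first frame) are fitted
independently. Whether they should share information is an open modeling
question; fitting independently is the simpler contract and is what the
additivity invariant requires.

### Iterative polynomial baseline (`iterpoly`)

Modified-polyfit family. Defaults: polynomial order 12, presmoothing 20
(read as a 20-point moving-average window applied once, before the first
iteration — a "presmoothing factor" names a single scalar, and a window
length is the standard reading), convergence when the working spectrum
changes by < 10⁻⁴ of its dynamic range, at most 100 iterations
(non-convergence is flagged, the best iterate returned). Each iteration
performs a least-squares polynomial fit and takes the pointwise minimum of
fit and working spectrum, truncating peaks from above. Implementation
notes:

- the fit uses an orthonormal (QR) polynomial basis on a pixel coordinate
  scaled to [−1, 1]; this keeps order-12 fits numerically stable and — since
  the projection matrix never changes — makes each iteration a single
  matrix product (~3 ms per cell decomposition);
- the procedure is exactly equivariant to adding a constant;
- at convergence the fitted curve can exceed the smoothed input by a small
  amount (polynomial ringing at truncated peak flanks, observed ≈ 0.1% of
  the dynamic range); tests budget 0.5%;
- because the pointwise-minimum step is one-sided, the converged baseline
  tracks the lower envelope of noise rather than its mean; the Raman
  residual on peak-free noisy input therefore has slightly positive mean
  and RMS ≲ 1.5× the noise RMS.

### Arc-corrected hull baseline (`archull`)

For continua too curved near the carotenoid bands for a polynomial. A plain
lower convex hull cannot follow a concave-down (dome) baseline — it
short-circuits the dome with the endpoint chord — so the gross curvature is
first removed with a circular arc and the hull applied to the residual:

1. median-filter the spectrum (window n/8) to suppress peaks;
2. find the interior point of the filtered profile **farthest from the
   endpoint chord** (either side); if its deviation is < 2% of the dynamic
   range, treat the baseline as straight and return the plain lower convex
   hull (exact for linear baselines with positive peaks);
3. otherwise fit a circle through the two endpoints and that point, in
   scaled coordinates (the y-unit is shrunk when the deviation approaches
   half the chord so the arc remains single-valued in x; degenerate or
   multi-branch geometry falls back to the plain hull);
4. baseline = lower convex hull of (spectrum − arc) + arc.

This reconstructs the *behavior* of proprietary "arc hull" routines, not
any published algorithm, and is documented as such. The farthest-from-chord
choice of the third point (rather than, say, the global minimum) is
deliberate: for a dome-shaped baseline with positive peaks the global
minimum is an endpoint, which degenerates the arc; the farthest interior
point of the peak-suppressed profile captures the dome apex and is what
makes the arc correction actually outperform the plain hull on concave-down
continua. The result never exceeds the input at any pixel.

## Peak analysis

ν₁ and ν₂ are fitted by nonlinear least squares with a single Lorentzian
plus constant offset (baselined spectra retain small residual offsets, so
the offset term is kept even though an ideal Raman component has none).
Default windows: ν₁ ∈ [1,480, 1,560], ν₂ ∈ [1,110, 1,180] cm⁻¹ — the band
positions themselves are only known to ~1,500/~1,150 a priori, so the
windows are configurable. Initialization: center at the window argmax,
Γ = 15 cm⁻¹, offset at the window minimum. A fit is rejected (with reason)
when the optimizer fails or the center pins at a window edge; rejected fits
carry `success=False` rather than raising, so one bad cell never kills a
run.

`measure_fwhm` is a separate, fit-free width: linear interpolation of
half-maximum crossings with the window minimum as local baseline. It is
the honest width for bands broadened by multiple carotenoid species, where
a single Lorentzian understates the width. Note the window-minimum
convention makes the result mildly window-dependent (Lorentzian tails raise
the minimum in narrow windows); tests use windows wide enough that the
effect is < 0.2 cm⁻¹.

SNR = signal ÷ RMS of the silent-region (2,204–2,274 cm⁻¹) intensities.
The signal statistic is the mean of n = 5 points (configurable 3–7; the
number actually used is recorded, e.g. at axis edges) centered on the pixel
nearest the fitted center; `max` replaces `mean` in environmental-sample
mode, where weak peaks on unknown backgrounds make the mean fragile. The
filter excludes records with SNR strictly below threshold — 2.0 for
cultured model organisms, 2.5 for environmental samples — so a record at
exactly the threshold is kept.

## Quantification

All scalar scores share one internal standard: the Euclidean norm of the
C–H stretching region of the **last** frame, Savitzky–Golay smoothed
(15 points, order 2). The C–H region default is [2,800, 3,022] cm⁻¹ (up to
the axis limit); the exact bounds are a convention, configurable. Using the
last frame minimizes the bleachable contribution to the standard; using a
norm makes every score invariant to a global detector gain.

- Normalized peak intensity: mean of n points around the fitted center ÷
  C–H norm.
- Species-average spectrum: each Raman component ÷ its ν₁ intensity
  (fitted amplitude + offset at the center by default; raw window max as a
  fallback convention), then the pixelwise mean; spectra with non-positive
  ν₁ intensity are excluded with a log entry. The output's ν₁ intensity is
  1 within ~2%.
- Autofluorescence intensity: max of the AF component in 737–776 nm ÷ C–H
  norm, no smoothing (smoothing the already-smooth baseline-of-difference
  would add a convention without adding robustness).
- AF threshold: the maximum AF intensity of a nonphototrophic control
  population (n = 25 in the default design); positivity is **strict**
  inequality, so the defining control cell is itself negative.

## Autofluorescence shape classification

Shapes, not intensities, are classified: AF components are truncated to
665–775 nm (dropping baseline-fit divergence at the axis ends), min–max
rescaled to [0, 1] per cell (constant rows are rejected with a log entry),
mean-centered (no variance scaling — rows are already on a common [0, 1]
scale) and embedded with 7-component PCA. X-means clusters the scores:
k-means refinement (centroid-change tolerance 10⁻⁴) alternates with
tentative two-way splits of every cluster, a split being kept when the
two-cluster BIC of that cluster's points exceeds its one-cluster BIC;
the process stops when no split is accepted or k reaches k_max.

The BIC is the spherical-Gaussian k-means likelihood with the parameter
penalty charged **per cluster**, the convention of the widely used
X-means implementations in Python clustering libraries. The choice matters:
with the penalty charged once per model, splitting is cheap enough that
X-means shatters genuinely single clusters whose within-cluster covariance
is anisotropic — and AF-shape clusters are intrinsically anisotropic here,
because the AF component is a polynomial baseline fit whose errors live in
a few smooth modes. The per-cluster penalty is conservative, recovers the
planted structure in the synthetic populations, and still splits merged
spherical clusters reliably. Defaults: k_init = 2, k_max = 20,
min_cluster_size = 2 (clusters below twice that size are never split);
all defaults and the seed are recorded in the result. Clustering is
deterministic given the seed.

Hierarchical clustering (Ward linkage, Euclidean metric by default — both
conventions, neither forced by the data) is provided for cross-checking
cluster structure on the same prepared matrix.

## Group statistics

Kruskal–Wallis H with mid-ranks and tie correction (degenerate all-equal
input returns H = 0, p = 1); p from χ² with k − 1 df. Pairwise comparisons
follow Dunn's large-sample rank procedure in the Hollander–Wolfe
formulation: Z_ij = (R̄_i − R̄_j) / √[(N(N+1)/12 − T)(1/n_i + 1/n_j)] with
the tie term T = Σ(t³−t)/(12(N−1)), declared different when
|Z_ij| ≥ z_{1−α/(k(k−1))}. The adjustment is single-step (no Holm-type
stepping) — the simplest reading of the named procedure; a stepwise variant
would only increase power, not validity. Under the global null the
familywise error is controlled at α (measured ≈ 0.04–0.05 at α = 0.05 over
2,000 replicates).

The compact letter display uses insert-and-absorb: start with one column
holding all groups; for each declared difference split every column
containing both members; deduplicate and absorb columns contained in
others. By construction groups sharing no letter are exactly the declared
differences.

## Synthetic data

The generator emulates the statistical structure the analysis assumes —
per frame t ∈ {0, 1, 2}:

    I_t = R0 · e^(−k_R t) + F0 · e^(−k_F t) + B + ε,   ε ~ N(0, σ²)

with Raman bands defined in shift space (Lorentzians at the profile's
ν₁/ν₂/ν₃), fluorescence defined in **wavelength** space (broad Gaussian
bands, optionally a sigmoidal rise toward 780 nm as in
bacteriochlorophyll-a-type emission) and resampled onto the pixel grid, and
a non-bleaching background B holding a constant offset and the biomass C–H
band at ~2,930 cm⁻¹. Bleaching is single-exponential per frame (the real
kinetics are not characterized; one rate per component is the minimal
model), with fluorescence bleaching at least as fast as the Raman signal in
default scenarios (k_F = 0.8, k_R = 0.05 per frame). Default noise is
additive Gaussian with σ = 1 detector count (Poisson counting noise is
available for realism). Populations draw per-cell profiles from mixture
weights and jitter amplitudes lognormally with CV = 0.25 — a typical
cell-to-cell pigment variability for clonal cultures.

Presets span ν₁ 1,503–1,531 cm⁻¹ — spirilloxanthin-like (1,505/1,150),
spheroidene-like (1,519/1,156), a bacteriochlorophyll-b producer
(1,528/1,155), a pink Methylobacterium-like isolate (1,507/1,152), a
long-chain environmental carotenoid (1,503/1,149), β-carotene-like
(1,523/1,157), flexirubin-like (1,531/1,133) and a pigment-free
nonphototroph — with three autofluorescence shape families (690 nm band +
760 nm shoulder + long-wavelength rise; 690 nm band without rise; a single
730 nm band).

What the simulations do **not** emulate: cosmic-ray spikes, detector
nonlinearity and etaloning, substrate backgrounds with structure, focus
drift within a series, multi-exponential bleaching, and real biological
shape variability within a species beyond amplitude jitter. Passing tests
therefore demonstrate the *analysis logic* (unmixing, estimation,
filtering, clustering, inference) under the stated measurement model, not
robustness to every instrumental artifact.

## Problem sizes and numerical conventions

The test suite and the acceptance script use: 1,000 cells for the
additivity check, 200 cells for peak-center bias, 75 cells (3 × 25, the
per-strain design size) for cluster recovery with five replicate
populations in the acceptance script, 25 controls for the AF threshold,
2,000 null replicates for the familywise-error measurement, and 100–500
replicate fits for Monte-Carlo error bounds. Key tolerances: additivity to
machine precision (< 10⁻¹² relative); baseline RMSE < 3% of peak amplitude
on order-5 continua; peak-center bias < 0.5 cm⁻¹ at SNR ≥ 5; shift ↔
wavelength round trip < 10⁻⁶ cm⁻¹. Ties in ranks use mid-ranks throughout;
degenerate inputs (constant spectra, zero silent-region variance, empty
control sets) raise informative errors rather than returning silent
defaults.

## Known limitations

- The archull routine is a behavioral reconstruction of an unpublished
  algorithm; its output should be compared against `iterpoly` when both are
  plausible.
- The AF component inherits the smoothness of the baseline fit: sharp
  fluorescence features narrower than the polynomial can follow are
  attributed partly to the Raman component.
- The SNR statistic assumes the silent region is signal-free; samples with
  bands in 2,204–2,274 cm⁻¹ (e.g., deuterated or nitrile-labeled cells)
  need a different noise window.
- X-means results depend on the BIC convention (see above); k should be
  read as a data-driven suggestion and checked against the hierarchical
  clustering view, as done here for the synthetic populations.
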