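# scraman

**Single-cell resonance-Raman / autofluorescence unmixing for pigmented
bacteria.**

Phototrophic and carotenoid-producing bacteria probed with a 632.8 nm He–Ne
laser emit two superposed signals: a broad autofluorescence continuum from
their photopigments (bacteriochlorophylls and relatives) and sharp
resonance-enhanced Raman bands from the conjugated polyene chain of their
carotenoids (ν₁ C=C ≈ 1,500 cm⁻¹, ν₂ C–C ≈ 1,150 cm⁻¹, ν₃ ≈ 1,000 cm⁻¹).
Both components photobleach under continued illumination, the fluorescence
typically faster. `scraman` separates them from a time series of three
consecutive 30 s exposures per cell and turns the components into per-cell
descriptors, population clusters, and group statistics. It is written for
microbial ecologists and spectroscopists who want a tested, scriptable
version of this analysis — including for environmental samples (e.g.,
phyllosphere cell suspensions) where no cultured reference exists.

## Method

For each cell with frames $I_0, I_1, I_2$ on a shared 1,600-pixel axis
(uniform in wavelength over 660–3,022 cm⁻¹, i.e. ~661–783 nm):

1. **Difference spectrum** $D = I_0 - I_2$ contains only the photobleaching
   (electronically resonant) part of the signal.
2. **Autofluorescence component** = baseline of $D$, fitted with an
   iterative least-squares polynomial (order 12, 20-point presmoothing):
   each iteration fits a polynomial, replaces fitted values exceeding the
   working spectrum by the working spectrum (truncating the Raman peaks),
   and feeds the result back in. An arc-corrected lower-convex-hull
   baseline (`archull`) is available for strongly curved continua.
3. **Raman component** $R = I_0 - \mathrm{baseline}(I_0)$, so that
   $R + \mathrm{baseline}(I_0) \equiv I_0$ exactly.
4. **Peak descriptors**: single-Lorentzian fits
   $A\,(\Gamma/2)^2 / ((\tilde\nu - \tilde\nu_0)^2 + (\Gamma/2)^2) + c$
   of the ν₁ and ν₂ bands; SNR = mean (or max) of 3–7 points around the
   peak ÷ RMS of the silent region 2,204–2,274 cm⁻¹ (50 pixels); cells with
   SNR < 2.0 (cultures) or < 2.5 (environmental) are excluded.
5. **Scores**: peak and autofluorescence intensities are normalized to the
   Euclidean norm of the Savitzky–Golay-smoothed (15 points, order 2)
   C–H stretching region of the *last* frame, so detector gain cancels.
   Autofluorescence intensity = max of the AF component in 737–776 nm ÷
   that norm; a cell is AF-positive when its intensity strictly exceeds the
   maximum of a nonphototrophic control population.
6. **Shape classification**: AF components truncated to 665–775 nm, min–max
   normalized, embedded with 7-component PCA and clustered with X-means
   (BIC-scored splitting, tolerance 10⁻⁴), plus Ward hierarchical
   clustering.
7. **Statistics**: Kruskal–Wallis omnibus test and Dunn's pairwise rank
   comparisons (Hollander–Wolfe formulation, single-step
   $\alpha/(k(k-1))$ adjustment) summarized as a compact letter display.

A synthetic-data module generates three-frame populations with known ground
truth (per-component exponential bleaching, Gaussian or Poisson noise,
lognormal cell-to-cell variability, named species presets spanning
ν₁ 1,503–1,531 cm⁻¹ and three autofluorescence shape families), standing in
for the instrument in every test.

## Worked example

```python
from scraman import RunConfig, analyze_cells, simulate_population
from scraman.synthetic_data import preset

profiles = [preset("spirilloxanthin_anaerobe"),   # nu1 1,505, BChl-a-like AF
            preset("spheroidene_anaerobe"),       # nu1 1,519, BChl-a-like AF
            preset("bchl_b_anaerobe")]            # nu1 1,528, BChl-b-like AF
pops = [simulate_population([p], n_cells=25, seed=10 + i)
        for i, p in enumerate(profiles)]
# ... relabel cell ids per species, build a cell_id -> species mapping ...
controls = simulate_population([preset("nonphototroph")], n_cells=25, seed=99)
result = analyze_cells(cells, RunConfig(seed=1), groups=groups,
                       control_cells=controls.cells)
```

Output (75 cells, 25 per species):

```
                          nu1_center  nu2_center  snr_nu1  af_intensity
group
bchl_b_anaerobe              1528.02     1155.04    54.00          0.03
spheroidene_anaerobe         1518.99     1156.02    50.73          0.09
spirilloxanthin_anaerobe     1504.99     1150.01    46.90          0.08

SNR filter pass: 75 / 75
AF-positive cells: 75
AF shape clusters: k = 3
nu1 intensity: H = 26.3, p ~ 2e-06
letters: {'spirilloxanthin_anaerobe': 'a', 'spheroidene_anaerobe': 'a',
          'bchl_b_anaerobe': 'b'}
```

The fitted ν₁/ν₂ centers recover each preset's true band positions to
well under a wavenumber; X-means finds the three autofluorescence shape
families without being told k; and the letter display says the
bchl-b-like species differs in normalized ν₁ intensity from the other two,
which are mutually indistinguishable at α = 0.05.

The same pipeline runs from the shell:

```sh
scraman simulate --preset spirilloxanthin_anaerobe --preset spheroidene_anaerobe \
        --n 50 --seed 7 --out data/
scraman run-all --input-dir data/ --groups-csv data/truth.csv --out out/ --seed 7
```

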