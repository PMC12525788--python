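# Methods

This note documents the models, conventions and numerical choices behind
`nirseed`, and what the synthetic studies do and do not establish about
real seed spectra.

## Spectra and grid

Spectra are absorbance log(1/R) on a uniform ascending wavelength grid.
The canonical grid is 400–2498 nm at 2 nm (1050 points): scanning
monochromators of the relevant instrument family emit an even final
wavelength, so the nominal "400–2500 nm" range ends at 2498 nm. Any
uniform 2 nm grid is accepted; missing values inside a spectrum are not —
imputation would silently distort derivative spectra, so a row with a gap
is rejected with its index reported.

## Math treatment

The preprocessing recipe is applied in a fixed order:
**window-restrict → SNV → detrend → derivative**, matching the
conventional ordering of scatter correction before derivatization. The
default window is 1100–2498 nm; the visible/short-NIR region below
1100 nm carries colour variation that does not help the analyte model.

* **SNV** centers each spectrum and scales it to unit sample SD
  (ddof = 1). A numerically constant spectrum (SD at rounding level,
  threshold `1e-12·(|mean|+1)`) is a hard error.
* **Detrend** subtracts the least-squares polynomial in wavelength,
  degree 2 by default (classic SNV-detrend). Detrend is applied to the
  SNV output sequentially; the two are not assumed interchangeable.
  The basis is evaluated on a half-range-scaled axis to keep the
  Vandermonde well conditioned.
* **Gap-segment derivative** implements the WinISI-style tuple
  *(d, g, s1, s2)*: a centered moving average over *s1* points, a second
  pass over *s2* points (*s2* = 1 means none), then *d* applications of a
  centered gap difference. For gap *g* the stencil offset is
  *h = round(g/2)* (half-up, so *h* = 3 for *g* = 5) on each side, and the
  first difference is scaled by the wavelength distance between the
  stencil points, `(x[i+h] − x[i−h]) / (2·h·Δλ)`. Under this scaling the
  second derivative of a·λ² is exactly 2a; the absolute scale cancels in
  regression but is documented and stable. Edges with incomplete stencils
  are trimmed, never padded — padding fabricates signal exactly where the
  peak analyses read. The default treatment (2, 5, 5, 1) therefore maps a
  700-point window to 684 surviving points.

## Modified PLS

`MPLS` is single-response PLS1 fitted by NIPALS: center X and y; per
factor take the weight along the X-residual/y-residual covariance,
project, and deflate both residuals. With `modified=True` (the default),
after each factor every wavelength's residual column and the y residual
are divided by their standard deviations before the next factor is
extracted (the Shenk–Westerhaus modification); the per-factor scale
vectors are stored and replayed at prediction. Zero-variance residual
columns keep scale 1 to avoid division blow-ups. `modified=False` is
textbook PLS1 and is the bridge used to cross-check the implementation
against an independent PLS library in the tests.

The whole prediction path is affine, so each fitted model also carries a
collapsed coefficient vector; factor-wise and collapsed predictions agree
to ~1e-10 and the invariant is tested. Models serialize to a versioned
JSON document (grid, treatment, centers, factors, scales, coefficients).

**Cross-validation.** Samples are partitioned into `n_groups = 5`
near-equal groups by a seeded random permutation. For each left-out group
the model is refitted on the remainder and the group predicted at every
factor count; SECV(f) is the RMS of the pooled out-of-group residuals.
The selected factor count is the smallest *f* with
SECV(f) ≤ 1.02 · min SECV (a parsimony rule guarding against overfitted
factor counts), capped at `max_factors = 16` and at the rank bound
min(n−1, p). An optional WinISI-style outlier pass
(|CV residual| > 2.5 · SECV) is available but off by default, since the
reference analysis does not describe one.

## Statistics

With e = predicted − reference:

* SEC = √(Σe²/(n−f−1)) — the extra degree of freedom accounts for
  centering.
* SECV = √(mean(e²)) over pooled CV residuals, no bias correction.
* SEP (external validation) is bias-corrected: bias = ē,
  SEP = √(Σ(e−ē)²/(n−1)).
* 1-VR = 1 − Var(e)/Var(reference) with population variances, floored at
  0 for reporting. The population-variance convention is a documented
  constant; the exact divisor of the historical software is not
  recoverable, and the choice only matters at third-decimal level.
* R² for external validation is the squared Pearson correlation (hence
  identical on raw and bias-corrected predictions).

## Selection predictability

At cutoff q %, k = max(1, round(q·n/100)) with half-up rounding (5 % of
179 → 8.95 → 9, matching the implied denominators of the reference
workflow). The match is 100·|top-k(pred) ∩ top-k(ref)|/k. Ties crossing
the k-th rank are broken deterministically by sample id and flagged in
the report. For an uninformative predictor the expected match is the
hypergeometric mean 100·k/n, which the tests verify by simulation. Under
the expansion strategies, selection is scored only on the samples not
absorbed into the calibration.

## Wavelength significance

The screening heuristic averages the processed (second-derivative)
spectra of the 50 lowest- and 50 highest-reference-TMQ samples and takes
the per-wavelength SD between the two averages — for two values simply
|a−b|/√2. Peaks are local maxima ranked by height with a minimum
separation of 20 nm (default), chosen to suppress shoulder
double-counting while keeping genuinely adjacent analyte bands (≥16 nm
apart) distinguishable.

## Synthetic studies

The generator emulates a three-year breeding study:

* **TMQ marginals** per year are reflected gammas,
  `tmq = max − Gamma(shape = 4, scale = (max−mean)/shape)` clipped to the
  year's range — a left-skewed distribution, as expected of material
  selected for high TMQ. Defaults: 2021 n = 288, mean 7.75, range
  0.68–14.46; 2022 n = 313, mean 12.00, range 1.74–17.30; 2023 n = 179,
  mean 8.75, range 1.08–13.49 (mg g⁻¹).
* **Analyte bands**: Gaussians at 1650, 2090, 2106, 2228, 2256, 2272 and
  2294 nm (σ 8–10 nm) whose amplitude is linear in TMQ. The spectral
  expression of concentration is imperfect: the band driver is
  `tmq + N(0, 0.65)` mg g⁻¹ per sample (particle size, packing, matrix
  interactions), and this — together with the 0.4 mg g⁻¹ reference
  error — is what bounds the attainable calibration accuracy at a SECV
  near 0.9 mg g⁻¹.
* **Matrix constituents**: oil-like (1726/2308 nm), protein-like
  (2180 nm), water-like (1450/1940 nm) and carbohydrate-like
  (2100/2276 nm) bands with independent log-normal per-sample loadings.
  Positions are literature-typical for seed tissue, not fitted to any
  dataset; the carbohydrate bands deliberately overlap the analyte
  regions so the regression must use contrast wavelengths rather than a
  single band height.
* **Scatter and noise**: per-sample multiplicative (SD 0.05) and additive
  (SD 0.02) scatter, a linear baseline tilt, and iid absorbance noise
  (SD 3e-4).
* **Year effects**: each year adds a season-specific signature composed
  of three independent band-pair components with per-sample gamma
  loadings (CV = 1.0) around the year's offset scale (0 for 2021, 0.003
  for 2022, 0.020 for 2023). The components are narrow enough to survive
  the second-derivative treatment — a constant or affine offset would be
  annihilated by SNV/detrend/derivative and could never produce the
  across-season bias the expansion strategies exist to repair. The mean
  loading produces the validation bias; the loading variance produces
  rank noise that calibration expansion progressively removes, which is
  why the selection match improves from strategy (a) to (c).
* **Reference values** are truth + N(0, 0.4) mg g⁻¹, clipped at 0,
  mimicking HPLC measurement error.

Defaults were fixed once by pilot runs so that the default study sits in
the realistic regime the pipeline is meant for (cross-validation 1-VR
≈ 0.94, SECV ≈ 0.9 mg g⁻¹, uncorrected third-year SEP ≈ 1.3 mg g⁻¹ with
a clear positive bias) and were not revisited afterwards.

**What passing tests show — and do not.** The synthetic studies establish
that the implementation is correct (exact oracles), that the pipeline
recovers known structure (band positions, transfer bias, expansion
benefit, selection ordering), and that factor selection does not
manufacture signal from noise. They do not establish instrument-level
realism: real seed spectra have correlated constituent loadings,
wavelength-dependent noise, temperature/moisture drift and nonlinear
scatter that the generator does not model, so the numbers obtained here
characterize the method, not any particular instrument or crop dataset.

## Determinism and problem sizes

A single root seed expands into named substreams (simulate / cv / split),
so strategy comparisons share one simulated dataset and two runs with the
same seed are byte-identical. The default study (288/313/179 samples,
1050-point spectra) runs the full pipeline in a few seconds; tests use
scaled-down studies (40–120 samples) where the property under test does
not depend on the full sample size, and the multi-seed robustness checks
use 20 replicate seeds.

## Known limitations

* The residual-standardization variant of PLS implemented here follows
  the published description of the modification; the historical
  software's exact cross-validation grouping and factor-selection
  heuristics are proprietary, and ours are documented choices, not
  claimed identical.
* PLS2, MSC/OSC preprocessing, variable-selection PLS and formal
  variable-importance measures (VIP) are out of scope.
* The generator's constituent loadings are independent across
  constituents; real seed composition is correlated.
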