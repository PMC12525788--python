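# nirseed

Near-infrared reflectance spectroscopy (NIRS) chemometrics for quantifying
**thymoquinone (TMQ)** — the main bioactive compound of black cumin
(*Nigella sativa* L.) — in intact seeds, without solvent extraction or
HPLC. The target users are plant breeders and analytical labs that need to
screen hundreds of seed lots per season and want a calibration workflow
whose every statistic is reproducible from per-sample predictions.

## What it does

Spectra are absorbance log(1/R) on a uniform 2 nm grid (400–2498 nm).
The pipeline implements the full calibration life cycle:

1. **Math treatment** — standard normal variate (SNV), second-degree
   detrend, and a gap-segment second derivative with the WinISI-style
   tuple *(d, g, s1, s2) = (2, 5, 5, 1)*, on the 1100–2498 nm window.
2. **Modified partial least squares (MPLS)** — PLS1 fitted by NIPALS
   where, after each latent factor, the spectral and reference residuals
   are standardized before the next factor is extracted
   (Shenk–Westerhaus). Grouped cross-validation selects the factor count
   (smallest *f* within 2 % of the SECV minimum) and yields SECV and the
   "one minus variance ratio" (1-VR) estimate of R².
3. **Multi-year validation** — a two-year pooled calibration validated on
   a third harvest under three strategies: (a) all third-year samples held
   out, (b) 25 % moved into the calibration and the model refit,
   (c) 50 % moved in; external validation reports the bias-corrected
   standard error of prediction, SEP = √(Σ(e−ē)²/(n−1)).
4. **Selection predictability** — the share of the reference (HPLC) top
   5/10/15 % of samples captured by the NIRS top fraction, the quantity a
   breeding program actually acts on.
5. **Wavelength significance** — SD profile between the average
   second-derivative spectra of the 50 lowest- and 50 highest-TMQ samples,
   with ranked peak localization.

Because no public spectral dataset exists for this crop, the package ships
a first-class synthetic generator (`nirseed.synthetic`) producing
three-year studies with TMQ-linked Gaussian absorption bands, matrix
constituents, scatter, instrument noise, season-specific spectral offsets
and noisy HPLC-like reference values — so every stage runs end-to-end
against known ground truth.

## Worked example

```python
from nirseed import StudyConfig, run_study
from nirseed.stats import render_table

out = run_study(StudyConfig(seed=1))   # simulate + calibrate + validate
print(out.calibration_cv.summary())
```

```
Modified PLS calibration
  samples:        601
  data points:    684
  latent factors: 2
  SEC:            0.857 mg/g
  R2:             0.943
  ...
  SECV:           0.867 mg/g
  1-VR:           0.941
```

The pooled two-year calibration (n = 601) explains ~94 % of the reference
variance in cross-validation with a SECV of 0.87 mg g⁻¹. The third-year
validation table shows the across-season transfer problem and its repair
by calibration expansion:

```
Type             Year                      n    Mean   Range       SE    R2
Validation       2023                      179  8.54   1.77–13.07  1.28  0.76
Validation       2023 (25% expanded)       134  8.46   1.77–12.63  0.90  0.87
Validation       2023 (50% expanded)       89   8.30   1.77–12.24  0.81  0.89
```

SEP drops from 1.28 to 0.81 mg g⁻¹ as third-year samples enter the
calibration, and the uncorrected run carries a bias near +1 mg g⁻¹ — the
signature of a season-specific spectral shift. The wavelength analysis on
the same run localizes the analyte:

```python
print(out.peaks)     # [2106.0, 2258.0]  (nm)
```

the two SD-profile maxima falling on the injected TMQ band regions
(C–H/C=O combination near 2106 nm, methylene combination near 2254 nm).

A shell workflow with the same stages is available as the `nirseed` CLI
(`simulate`, `calibrate`, `validate`, `select`, `wavelengths`); every
table it prints is backed by a per-sample prediction CSV.

## Layout

| module | contents |
| --- | --- |
| `nirseed.io` | `SpectraSet` container, CSV dialect, reference alignment |
| `nirseed.preprocess` | SNV, detrend, gap-segment derivative, `MathTreatment` |
| `nirseed.mpls` | `MPLS` model, `MPLSResults`, grouped CV, serialization |
| `nirseed.stats` | SEC / SECV / bias-corrected SEP / 1-VR / R² reports |
| `nirseed.selection` | top-fraction selection match analysis |
| `nirseed.wavelengths` | group averages, SD profile, peak finding |
| `nirseed.synthetic` | seed-spectra generator with known ground truth |
| `nirseed.pipeline` | study orchestration; `nirseed.cli` the CLI |

See `docs/methods.md` for the model details, the simulator's assumptions,
and the numerical choices.
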