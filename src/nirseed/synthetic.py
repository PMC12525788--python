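"""Synthetic black cumin seed spectra with known thymoquinone ground truth.

No public spectral dataset for this crop exists, so the pipeline is
exercised on simulated three-year studies whose statistical structure
mirrors what the analysis assumes:

* per-year TMQ distributions (sample size, mean, range, left skew) set to
  the study conditions of the 2021/2022/2023 harvests;
* analyte absorption bands — Gaussians whose amplitude scales linearly
  with TMQ concentration — at the thymoquinone-associated centers
  (1650, 2090, 2106, 2228, 2256, 2272, 2294 nm);
* matrix constituents (oil-, protein- and water-like bands at
  literature-typical positions) with random per-sample loadings;
* multiplicative/additive scatter, baseline tilt, instrument noise;
* a smooth year-specific spectral offset that survives derivative
  preprocessing, inducing the across-season prediction bias that
  calibration expansion is meant to repair;
* reference values contaminated with "HPLC" measurement error.

The TMQ marginal is a reflected gamma: ``tmq = max − Gamma(shape, scale)``
clipped to the year's range, giving the left-skewed histogram expected of
a breeding population selected for high TMQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CANONICAL_GRID, SpectraSet

__all__ = [
    "BandModel",
    "YearParams",
    "SyntheticConfig",
    "SyntheticStudy",
    "sample_tmq",
    "generate_spectrum",
    "generate_study",
]


@dataclass(frozen=True)
class BandModel:
    """One Gaussian absorption band.

    ``amplitude`` is absorbance per mg g⁻¹ for analyte bands, absorbance
    per unit constituent loading otherwise.
    """

    center: float  # nm
    width: float   # Gaussian sigma, nm
    amplitude: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("band width must be > 0")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((grid - self.center) / self.width) ** 2)


@dataclass(frozen=True)
class YearParams:
    """Per-year TMQ distribution targets and spectral offset."""

    n: int
    mean: float          # mg/g
    min: float           # mg/g
    max: float           # mg/g
    gamma_shape: float = 4.0
    offset_scale: float = 0.0   # absorbance multiplier of the offset shape

    def __post_init__(self):
        if not self.min <= self.mean <= self.max:
            raise ValueError(
                f"infeasible year params: mean {self.mean} outside "
                f"[{self.min}, {self.max}]"
            )


#: Thymoquinone-linked band set: the 1650 nm first-overtone region plus the
#: 2038–2114 and 2226–2418 nm combination-band regions.
DEFAULT_TMQ_BANDS = (
    BandModel(1650.0, 10.0, 0.0020),
    BandModel(2090.0, 8.0, 0.0035),
    BandModel(2106.0, 8.0, 0.0045),
    BandModel(2228.0, 9.0, 0.0025),
    BandModel(2256.0, 9.0, 0.0040),
    BandModel(2272.0, 9.0, 0.0025),
    BandModel(2294.0, 9.0, 0.0020),
)

#: Matrix constituents at literature-typical positions: seed oil C–H bands
#: near 1726/2308 nm, protein N–H near 2180 nm, water O–H near 1450/1940 nm.
DEFAULT_MATRIX_BANDS = (
    ("oil", (BandModel(1726.0, 18.0, 0.060), BandModel(2308.0, 20.0, 0.050))),
    ("protein", (BandModel(2180.0, 25.0, 0.045),)),
    ("water", (BandModel(1450.0, 35.0, 0.070), BandModel(1940.0, 40.0, 0.090))),
    # starch/carbohydrate C–H/O–H combinations overlapping the analyte
    # regions: these force the regression to use contrast wavelengths
    # rather than a single band height.
    ("carbohydrate", (BandModel(2100.0, 22.0, 0.040),
                      BandModel(2276.0, 24.0, 0.035))),
)

#: Year-offset signature: several independent season-specific constituent
#: components, each a set of bands with its own per-sample loading.  Band
#: widths are kept narrow enough to survive the second-derivative treatment
#: (broad humps are annihilated by it) and sit near the analyte-informative
#: regions, where a seasonal shift actually perturbs the calibration.  A
#: multi-component effect is deliberately harder to learn from a small
#: expansion subset than a single direction would be.
YEAR_OFFSET_COMPONENTS = (
    (BandModel(1700.0, 14.0, 1.0), BandModel(2100.0, 14.0, 0.8)),
    (BandModel(1940.0, 25.0, 0.6), BandModel(2260.0, 16.0, -0.7)),
    (BandModel(2050.0, 15.0, 0.5), BandModel(2330.0, 18.0, 0.6)),
)

DEFAULT_YEARS = {
    2021: YearParams(n=288, mean=7.75, min=0.68, max=14.46, offset_scale=0.0),
    2022: YearParams(n=313, mean=12.00, min=1.74, max=17.30, offset_scale=0.003),
    2023: YearParams(n=179, mean=8.75, min=1.08, max=13.49, offset_scale=0.020),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a simulated multi-year seed study."""

    years: dict = field(default_factory=lambda: dict(DEFAULT_YEARS))
    tmq_bands: tuple = DEFAULT_TMQ_BANDS
    matrix_bands: tuple = DEFAULT_MATRIX_BANDS
    matrix_loading_sigma: float = 0.25   # lognormal sigma of loadings
    scatter_mult_sd: float = 0.05        # multiplicative scatter SD
    scatter_add_sd: float = 0.02         # additive offset SD, absorbance
    scatter_tilt_sd: float = 1.5e-5      # per-nm linear tilt SD
    noise_sd: float = 3e-4               # iid absorbance noise
    spectral_tmq_noise_sd: float = 0.65  # mg/g; analyte-signal expression noise
    offset_loading_cv: float = 1.0       # per-sample spread of the year offset
    hplc_error_sd: float = 0.4           # reference error, mg/g
    seed: int = 0
    grid: np.ndarray = field(default_factory=lambda: CANONICAL_GRID.copy())

    def __post_init__(self):
        for name in ("matrix_loading_sigma", "scatter_mult_sd",
                     "scatter_add_sd", "scatter_tilt_sd", "noise_sd",
                     "spectral_tmq_noise_sd", "offset_loading_cv",
                     "hplc_error_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for b in self.tmq_bands:
            if not self.grid[0] <= b.center <= self.grid[-1]:
                raise ValueError(f"band center {b.center} nm outside grid")


def sample_tmq(params: YearParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n TMQ values from the year's left-skewed distribution.

    Reflected gamma: ``max − Gamma(shape, (max − mean)/shape)``, clipped to
    ``[min, max]``.  Matches the year mean to within a few percent and
    respects the range exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params.min == params.max:
        return np.full(n, params.min)
    scale = (params.max - params.mean) / params.gamma_shape
    g = rng.gamma(params.gamma_shape, scale, size=n)
    return np.clip(params.max - g, params.min, params.max)


def _baseline(grid: np.ndarray) -> np.ndarray:
    """Deterministic smooth seed-matrix baseline, absorbance units."""
    t = (grid - grid[0]) / (grid[-1] - grid[0])
    return 0.45 + 0.55 * t + 0.15 * t**2


def _offset_components(grid: np.ndarray) -> list[np.ndarray]:
    shapes = []
    for bands in YEAR_OFFSET_COMPONENTS:
        s = np.zeros_like(grid)
        for b in bands:
            s += b.profile(grid)
        shapes.append(s)
    return shapes


def generate_spectrum(
    tmq: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    *,
    offset_scale: float = 0.0,
    noise: bool = True,
    scatter: bool = True,
    matrix: bool = True,
) -> np.ndarray:
    """One absorbance spectrum for a seed sample of the given TMQ content.

    ``absorbance = baseline + Σ analyte_bands · tmq + Σ matrix_bands ·
    loading + year offset + scatter (α·x + β + γ·λ) + noise``.  The
    keyword switches exist for oracle tests (pure-band construction,
    linearity in TMQ).

    With ``noise=True`` the analyte contribution is driven by
    ``tmq + N(0, spectral_tmq_noise_sd)`` rather than tmq itself: the
    spectral expression of concentration is imperfect (particle size,
    packing, matrix interactions), which is what ultimately bounds the
    calibration accuracy.  The year offset's per-sample loading is
    gamma-distributed around ``offset_scale`` (CV ``offset_loading_cv``),
    i.e. a season-specific constituent whose amount varies from seed lot
    to seed lot.
    """
    grid = config.grid
    x = _baseline(grid).copy()
    tmq_expressed = tmq
    if noise and config.spectral_tmq_noise_sd > 0:
        tmq_expressed = tmq + rng.normal(0.0, config.spectral_tmq_noise_sd)
    for band in config.tmq_bands:
        x += band.profile(grid) * tmq_expressed
    if matrix:
        for _name, bands in config.matrix_bands:
            loading = rng.lognormal(0.0, config.matrix_loading_sigma)
            for band in bands:
                x += band.profile(grid) * loading
    if offset_scale != 0.0:
        cv = config.offset_loading_cv
        for shape in _offset_components(grid):
            loading = offset_scale
            if cv > 0:
                loading = offset_scale * rng.gamma(1.0 / cv**2, cv**2)
            x += loading * shape
    if scatter:
        alpha = 1.0 + rng.normal(0.0, config.scatter_mult_sd)
        beta = rng.normal(0.0, config.scatter_add_sd)
        gamma = rng.normal(0.0, config.scatter_tilt_sd)
        x = alpha * x + beta + gamma * (grid - grid.mean())
    if noise and config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=grid.size)
    return x


@dataclass
class SyntheticStudy:
    """Generated study: per-year spectra sets plus the noiseless truth."""

    sets: dict[int, SpectraSet]
    truth: dict[int, np.ndarray]
    config: SyntheticConfig

    def pooled(self, years) -> SpectraSet:
        return SpectraSet.concat([self.sets[int(y)] for y in years])


def generate_study(config: SyntheticConfig | None = None,
                   seed: int | None = None) -> SyntheticStudy:
    """Simulate the full multi-year study.

    Per year: TMQ truth from :func:`sample_tmq`, spectra from
    :func:`generate_spectrum` with the year's spectral offset, and noisy
    HPLC-like reference values ``truth + N(0, hplc_error_sd)``.  The same
    (config, seed) always yields a bit-identical study.
    """
    config = config or SyntheticConfig()
    root = config.seed if seed is None else seed
    ss = np.random.SeedSequence(root)
    sets: dict[int, SpectraSet] = {}
    truth: dict[int, np.ndarray] = {}
    children = ss.spawn(len(config.years))
    for child, (year, params) in zip(children, sorted(config.years.items())):
        rng = np.random.default_rng(child)
        tmq = sample_tmq(params, params.n, rng)
        spectra = np.vstack([
            generate_spectrum(t, config, rng, offset_scale=params.offset_scale)
            for t in tmq
        ])
        reference = tmq + rng.normal(0.0, config.hplc_error_sd, size=params.n)
        reference = np.clip(reference, 0.0, None)
        sets[year] = SpectraSet(
            wavelengths=config.grid,
            absorbance=spectra,
            sample_ids=np.array([f"{year}-{i:04d}" for i in range(params.n)],
                                dtype=object),
            years=np.full(params.n, year),
            reference=reference,
        )
        truth[year] = tmq
    return SyntheticStudy(sets=sets, truth=truth, config=config)
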