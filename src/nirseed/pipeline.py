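"""End-to-end study orchestration: calibrate, validate, select, localize.

The canonical experiment on a three-year seed study:

1. calibrate on the pooled first two years (MPLS + grouped CV),
2. validate on the third year under three strategies — (a) all samples
   held out, (b) 25% moved into the calibration pool and the model refit,
   (c) 50% moved in — with bias-corrected SEP on the remainder,
3. score selection predictability (top-5/10/15% match) on each strategy's
   evaluation subset,
4. locate TMQ-informative wavelengths from low/high group averages.

A single root seed drives everything through named substreams
(simulate / cv / split), so strategy comparisons share one simulated
dataset and two runs with the same seed are identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import SpectraSet
from .mpls import MPLS, CVResults
from .preprocess import MathTreatment, apply_math_treatment
from .selection import SelectionReport, selection_curve
from .stats import EvaluationReport, summarize
from .synthetic import SyntheticConfig, SyntheticStudy, generate_study
from .wavelengths import SDProfile, find_peaks, group_average, low_high_groups, sd_profile

__all__ = [
    "StudyConfig",
    "StrategyOutcome",
    "StudyOutcome",
    "derive_seeds",
    "run_calibration",
    "run_validation_strategy",
    "run_selection_analysis",
    "run_wavelength_analysis",
    "run_study",
]

logger = logging.getLogger("nirseed")

_SUBSTREAMS = ("simulate", "cv", "split")


def derive_seeds(root_seed: int) -> dict[str, int]:
    """Named 31-bit substream seeds derived from one root seed."""
    children = np.random.SeedSequence(root_seed).spawn(len(_SUBSTREAMS))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_SUBSTREAMS, children)
    }


@dataclass
class StudyConfig:
    """Configuration of one full study run."""

    treatment: MathTreatment = field(default_factory=MathTreatment)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    calibration_years: tuple[int, ...] = (2021, 2022)
    target_year: int = 2023
    cv_groups: int = 5
    max_factors: int = 16
    expand_fractions: tuple[float, ...] = (0.0, 0.25, 0.5)
    cutoffs: tuple[float, ...] = (5.0, 10.0, 15.0)
    seed: int = 0

    def __post_init__(self):
        for f in self.expand_fractions:
            if not 0.0 <= f < 1.0:
                raise ValueError("expand fractions must be in [0, 1)")
        for c in self.cutoffs:
            if not 0.0 < c < 100.0:
                raise ValueError("cutoffs must be in (0, 100) percent")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        kwargs = {}
        if "treatment" in d:
            kwargs["treatment"] = MathTreatment.from_dict(d["treatment"])
        if "synthetic" in d:
            syn = dict(d["synthetic"])
            if "years" in syn:
                from .synthetic import YearParams

                syn["years"] = {
                    int(y): (p if isinstance(p, YearParams) else YearParams(**p))
                    for y, p in syn["years"].items()
                }
            kwargs["synthetic"] = SyntheticConfig(**syn)
        for key in ("calibration_years", "target_year", "cv_groups",
                    "max_factors", "expand_fractions", "cutoffs", "seed"):
            if key in d:
                kwargs[key] = d[key]
        for key in ("calibration_years", "expand_fractions", "cutoffs"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def run_calibration(
    sets: dict[int, SpectraSet],
    years,
    *,
    treatment: MathTreatment | None = None,
    cv_groups: int = 5,
    max_factors: int = 16,
    cv_seed: int = 0,
) -> tuple[CVResults, list[EvaluationReport]]:
    """Pool the requested years, fit MPLS, cross-validate.

    Returns the CV results (whose ``.results`` is the final model fitted on
    the full pool at the selected factor count) and the calibration +
    cross-validation report rows.
    """
    years = sorted(int(y) for y in years)
    missing = [y for y in years if y not in sets]
    if missing:
        raise KeyError(f"years not present in the study: {missing}")
    pool = SpectraSet.concat([sets[y] for y in years])
    treatment = treatment or MathTreatment()
    model = MPLS.from_spectra(pool, treatment)
    cv = model.fit_cv(max_factors=max_factors, n_groups=cv_groups, seed=cv_seed)
    label = " + ".join(str(y) for y in years)
    reports = [cv.results.training_report(label), cv.cv_report(label)]
    logger.info(
        "calibration %s: n=%d, factors=%d, SEC=%.3f, SECV=%.3f, 1-VR=%.3f",
        label, model.nobs, cv.n_factors_selected,
        reports[0].se, cv.secv, cv.one_minus_vr,
    )
    return cv, reports


@dataclass
class StrategyOutcome:
    """One validation strategy: split, (re)fit, external validation."""

    expand_fraction: float
    validation_ids: np.ndarray
    validation_reference: np.ndarray
    validation_predicted: np.ndarray
    report: EvaluationReport
    cv: CVResults                      # updated model when expanding, else base
    cv_report: EvaluationReport | None  # present only when the model was refit
    selection: list[SelectionReport] | None = None


def run_validation_strategy(
    sets: dict[int, SpectraSet],
    base_cv: CVResults,
    calibration_years,
    target_year: int,
    expand_fraction: float,
    split_seed: int,
    *,
    treatment: MathTreatment | None = None,
    cv_groups: int = 5,
    max_factors: int = 16,
    cv_seed: int = 0,
) -> StrategyOutcome:
    """Validate (and optionally expand) the calibration on the target year.

    A seeded random split moves ``expand_fraction`` of the target-year
    samples into the calibration pool (refitting the model, with a new
    cross-validation row); the remainder is validated with bias-corrected
    SEP and R².  ``expand_fraction=0`` leaves the base model untouched.
    """
    if not 0.0 <= expand_fraction < 1.0:
        raise ValueError("expand_fraction must be in [0, 1)")
    target = sets[int(target_year)]
    n = len(target)
    n_expand = int(round(expand_fraction * n))
    if n - n_expand < 2:
        raise ValueError("split leaves fewer than 2 validation samples")
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(n)
    expand_idx, valid_idx = perm[:n_expand], perm[n_expand:]
    valid_set = target.subset(np.sort(valid_idx))

    cv_report = None
    if n_expand:
        pool = SpectraSet.concat(
            [sets[int(y)] for y in sorted(calibration_years)]
            + [target.subset(np.sort(expand_idx))]
        )
        model = MPLS.from_spectra(pool, treatment or MathTreatment())
        cv = model.fit_cv(max_factors=max_factors, n_groups=cv_groups,
                          seed=cv_seed)
        label = (" + ".join(str(y) for y in sorted(calibration_years))
                 + f" + {expand_fraction:.0%} of {target_year}")
        cv_report = cv.cv_report(label)
    else:
        cv = base_cv

    predicted = cv.results.predict(valid_set)
    report = summarize(valid_set.reference, predicted, "validation",
                       label=str(target_year))
    logger.info(
        "validation %s (expand %.0f%%): n=%d, SEP=%.3f, bias=%.3f, R2=%.3f",
        target_year, 100 * expand_fraction, report.n, report.se,
        report.bias, report.r2,
    )
    return StrategyOutcome(
        expand_fraction=expand_fraction,
        validation_ids=valid_set.sample_ids,
        validation_reference=valid_set.reference,
        validation_predicted=predicted,
        report=report,
        cv=cv,
        cv_report=cv_report,
    )


def run_selection_analysis(
    outcomes: list[StrategyOutcome], cutoffs=(5.0, 10.0, 15.0)
) -> dict[float, list[SelectionReport]]:
    """Top-q% selection match per (strategy, cutoff).

    Each strategy is scored on its own evaluation subset — the target-year
    samples *not* absorbed into the calibration — so the denominators
    shrink as the expansion fraction grows.
    """
    grid: dict[float, list[SelectionReport]] = {}
    for outcome in outcomes:
        reports = selection_curve(
            outcome.validation_predicted,
            outcome.validation_reference,
            cutoffs,
            ids=outcome.validation_ids,
        )
        outcome.selection = reports
        grid[outcome.expand_fraction] = reports
    return grid


def run_wavelength_analysis(
    pool: SpectraSet,
    *,
    treatment: MathTreatment | None = None,
    n_low: int = 50,
    n_high: int = 50,
    top_k: int = 2,
    min_separation: float = 20.0,
) -> tuple[SDProfile, list[float]]:
    """SD profile between low/high-TMQ group averages, with top peaks."""
    processed = apply_math_treatment(pool, treatment or MathTreatment())
    low_ids, high_ids = low_high_groups(processed, n_low, n_high)
    profile = sd_profile(
        group_average(processed, low_ids),
        group_average(processed, high_ids),
        processed.wavelengths,
    )
    peaks = find_peaks(profile, top_k=top_k, min_separation=min_separation)
    logger.info("wavelength analysis: top peaks at %s nm",
                ", ".join(f"{p:.0f}" for p in peaks))
    return profile, peaks


@dataclass
class StudyOutcome:
    """Everything one full run produces."""

    study: SyntheticStudy
    calibration_cv: CVResults
    calibration_reports: list[EvaluationReport]
    strategies: list[StrategyOutcome]
    selection_grid: dict[float, list[SelectionReport]]
    sd_profile: SDProfile
    peaks: list[float]
    seeds: dict[str, int]


def run_study(config: StudyConfig | None = None,
              study: SyntheticStudy | None = None) -> StudyOutcome:
    """Run the complete pipeline on a (simulated or supplied) study."""
    config = config or StudyConfig()
    seeds = derive_seeds(config.seed)
    if study is None:
        study = generate_study(config.synthetic, seed=seeds["simulate"])
    cv, cal_reports = run_calibration(
        study.sets, config.calibration_years,
        treatment=config.treatment, cv_groups=config.cv_groups,
        max_factors=config.max_factors, cv_seed=seeds["cv"],
    )
    strategies = [
        run_validation_strategy(
            study.sets, cv, config.calibration_years, config.target_year,
            fraction, seeds["split"],
            treatment=config.treatment, cv_groups=config.cv_groups,
            max_factors=config.max_factors, cv_seed=seeds["cv"],
        )
        for fraction in config.expand_fractions
    ]
    selection_grid = run_selection_analysis(strategies, config.cutoffs)
    pool = study.pooled(
        sorted({*config.calibration_years, config.target_year})
    )
    profile, peaks = run_wavelength_analysis(pool, treatment=config.treatment)
    return StudyOutcome(
        study=study,
        calibration_cv=cv,
        calibration_reports=cal_reports,
        strategies=strategies,
        selection_grid=selection_grid,
        sd_profile=profile,
        peaks=peaks,
        seeds=seeds,
    )
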