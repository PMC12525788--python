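"""Calibration and validation statistics for NIRS chemometrics.

Definitions follow standard near-infrared calibration practice:

* SEC — standard error of calibration, ``sqrt(Σe² / (n − f − 1))`` with
  ``f`` latent factors (the extra 1 accounts for centering).
* SECV — standard error of cross-validation, the root mean square of the
  pooled out-of-group residuals (no bias correction).
* SEP — standard error of prediction in external validation, reported
  after correction for bias: ``bias = mean(e)``,
  ``SEP = sqrt(Σ(e − bias)² / (n − 1))``.
* 1-VR — "one minus variance ratio", the cross-validation estimate of R²:
  ``1 − Var(residuals)/Var(reference)`` with population variances,
  floored at 0 for reporting.
* R² — squared Pearson correlation, used for external validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvaluationReport",
    "sec",
    "secv",
    "sep_bias_corrected",
    "one_minus_variance_ratio",
    "r_squared",
    "slope",
    "summarize",
]

KINDS = ("calibration", "cross-validation", "validation")


@dataclass(frozen=True)
class EvaluationReport:
    """One row of a calibration/validation statistics table.

    ``se`` is SEC, SECV or SEP depending on ``kind``; concentrations in
    mg g⁻¹ seed.
    """

    kind: str
    n: int
    mean: float
    range: tuple[float, float]
    se: float
    r2: float
    bias: float = 0.0
    slope: float = float("nan")
    n_factors: int | None = None
    label: str = ""

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.n < 2:
            raise ValueError("a report needs n >= 2 samples")
        if self.se < 0:
            raise ValueError("standard error must be >= 0")

    def row(self) -> dict:
        return {
            "Type": self.kind.capitalize(),
            "Year": self.label,
            "n": self.n,
            "Mean": round(self.mean, 2),
            "Range": f"{self.range[0]:.2f}–{self.range[1]:.2f}",
            "SE": round(self.se, 2),
            "R2": round(self.r2, 2),
        }

    def __str__(self) -> str:
        r = self.row()
        return "\t".join(str(r[k]) for k in ("Type", "Year", "n", "Mean",
                                             "Range", "SE", "R2"))


def _as_vector(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def sec(residuals, n_factors: int) -> float:
    """Standard error of calibration with ``n − f − 1`` degrees of freedom."""
    e = _as_vector(residuals, "residuals")
    dof = e.size - n_factors - 1
    if dof <= 0:
        raise ValueError(
            f"SEC needs n > f + 1 (n={e.size}, f={n_factors}): no degrees of freedom"
        )
    return float(np.sqrt(np.sum(e**2) / dof))


def secv(cv_residuals) -> float:
    """Standard error of cross-validation: RMS of pooled CV residuals."""
    e = _as_vector(cv_residuals, "cv_residuals")
    if e.size < 2:
        raise ValueError("SECV needs at least 2 residuals")
    return float(np.sqrt(np.mean(e**2)))


def sep_bias_corrected(errors) -> tuple[float, float]:
    """Bias-corrected standard error of prediction.

    *errors* are predicted − reference.  Returns ``(sep, bias)`` where
    ``bias = mean(e)`` and ``sep = sqrt(Σ(e − bias)²/(n − 1))``; a pure
    constant offset is absorbed entirely by the bias term.
    """
    e = _as_vector(errors, "errors")
    if e.size < 2:
        raise ValueError("SEP needs at least 2 errors")
    bias = float(np.mean(e))
    sep = float(np.sqrt(np.sum((e - bias) ** 2) / (e.size - 1)))
    return sep, bias


def one_minus_variance_ratio(cv_predictions, reference) -> float:
    """1-VR cross-validation statistic (population-variance convention).

    ``1 − Var(ref − pred)/Var(ref)``, floored at 0 for reporting: the
    cross-validation analogue of the coefficient of determination R².
    """
    pred = _as_vector(cv_predictions, "cv_predictions")
    ref = _as_vector(reference, "reference")
    if pred.size != ref.size:
        raise ValueError("predictions and reference must align")
    if ref.size < 2 or np.var(ref) == 0:
        raise ValueError("reference must be non-constant with n >= 2")
    ratio = np.var(ref - pred) / np.var(ref)
    return float(max(0.0, 1.0 - ratio))


def r_squared(predicted, reference) -> float:
    """Squared Pearson correlation between predicted and reference values."""
    pred = _as_vector(predicted, "predicted")
    ref = _as_vector(reference, "reference")
    if pred.size != ref.size or pred.size < 3:
        raise ValueError("need aligned vectors with n >= 3")
    if np.std(pred) == 0 or np.std(ref) == 0:
        raise ValueError("constant input has undefined correlation")
    r = np.corrcoef(pred, ref)[0, 1]
    return float(r**2)


def slope(predicted, reference) -> float:
    """Least-squares slope of reference on predicted (validation slope)."""
    pred = _as_vector(predicted, "predicted")
    ref = _as_vector(reference, "reference")
    vp = np.var(pred)
    if vp == 0:
        return float("nan")
    return float(np.cov(pred, ref, ddof=0)[0, 1] / vp)


def summarize(
    reference,
    predicted,
    kind: str,
    n_factors: int | None = None,
    label: str = "",
) -> EvaluationReport:
    """Build a full :class:`EvaluationReport` for one table row.

    ``kind`` selects the standard error: SEC (needs ``n_factors``) for
    calibration, SECV for cross-validation, bias-corrected SEP for
    validation.  ``mean`` and ``range`` always describe the reference
    sample.
    """
    ref = _as_vector(reference, "reference")
    pred = _as_vector(predicted, "predicted")
    if ref.size != pred.size:
        raise ValueError("reference and predicted must align")
    e = pred - ref
    bias = 0.0
    if kind == "calibration":
        if n_factors is None:
            raise ValueError("calibration SEC needs n_factors")
        se = sec(e, n_factors)
        r2 = r_squared(pred, ref)
    elif kind == "cross-validation":
        se = secv(e)
        r2 = one_minus_variance_ratio(pred, ref)
    elif kind == "validation":
        se, bias = sep_bias_corrected(e)
        r2 = r_squared(pred, ref)
    else:
        raise ValueError(f"kind must be one of {KINDS}")
    return EvaluationReport(
        kind=kind,
        n=int(ref.size),
        mean=float(ref.mean()),
        range=(float(ref.min()), float(ref.max())),
        se=se,
        r2=r2,
        bias=bias,
        slope=slope(pred, ref),
        n_factors=n_factors,
        label=label,
    )


def render_table(reports: list[EvaluationReport]) -> str:
    """Tab-separated statistics table (Type, Year, n, Mean, Range, SE, R²)."""
    header = "Type\tYear\tn\tMean\tRange\tSE\tR2"
    return "\n".join([header] + [str(r) for r in reports])
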