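"""Modified partial least squares (MPLS) regression for NIRS calibration.

The model is PLS1 fitted by NIPALS with the Shenk–Westerhaus modification:
after each latent factor is extracted and deflated, every wavelength's
residual column and the reference residual are standardized (divided by
their standard deviations) before the next factor is extracted.  The
per-factor scale vectors are stored so prediction replays the exact
training path.  ``modified=False`` gives textbook PLS1 and serves as the
bridge to independent implementations.

API follows the statsmodels convention: build an :class:`MPLS` model from
data, call :meth:`MPLS.fit` (or :meth:`MPLS.fit_cv` for grouped
cross-validation with automatic factor selection) and work with the
returned results object.

Example
-------
>>> model = MPLS.from_spectra(training_set, MathTreatment())
>>> cv = model.fit_cv(max_factors=16, n_groups=5, seed=7)
>>> cv.results.predict(new_set)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import GridError, SpectraSet
from .preprocess import MathTreatment, apply_math_treatment
from .stats import (
    EvaluationReport,
    one_minus_variance_ratio,
    secv,
    summarize,
)

__all__ = ["MPLS", "MPLSResults", "CVResults", "CVPlan"]

SERIALIZATION_VERSION = 1

#: Relative tolerance for the "within x of the SECV minimum" parsimony rule.
SECV_PARSIMONY = 1.02


@dataclass(frozen=True)
class CVPlan:
    """Seeded random partition of ``n`` samples into near-equal groups."""

    n_samples: int
    n_groups: int = 5
    seed: int = 0
    assignment: np.ndarray = field(default=None, compare=False)

    def __post_init__(self):
        if self.n_groups < 2:
            raise ValueError("cross-validation needs at least 2 groups")
        if self.n_samples < self.n_groups:
            raise ValueError(
                f"cannot split {self.n_samples} samples into {self.n_groups} groups"
            )
        if self.assignment is None:
            rng = np.random.default_rng(self.seed)
            a = np.arange(self.n_samples) % self.n_groups
            object.__setattr__(self, "assignment", rng.permutation(a))
        else:
            a = np.asarray(self.assignment)
            if a.shape != (self.n_samples,):
                raise ValueError("assignment must map every sample to a group")
            sizes = np.bincount(a, minlength=self.n_groups)
            if sizes.min() < 1:
                raise ValueError("every group needs at least one sample")
            object.__setattr__(self, "assignment", a)

    def groups(self):
        for g in range(self.n_groups):
            yield g, self.assignment == g


def _nipals_mpls(Xc: np.ndarray, yc: np.ndarray, n_factors: int, modified: bool):
    """Factor extraction on centered data; returns per-factor quantities.

    Returns dict with weights W (f×p), loadings P (f×p), y-loadings q (f),
    X scales SX (f×p), y scales sy (f), and the per-factor cumulative
    coefficient vectors B (f×p) on the original (centered, unscaled) scale.
    """
    n, p = Xc.shape
    W = np.empty((n_factors, p))
    P = np.empty((n_factors, p))
    q = np.empty(n_factors)
    SX = np.ones((n_factors, p))
    sy = np.ones(n_factors)
    B = np.empty((n_factors, p))

    X = Xc.copy()
    y = yc.copy()
    M = np.eye(p)          # maps original centered x-row -> current residual
    g = 1.0                # cumulative y scale: product of prior sy
    b = np.zeros(p)
    for f in range(n_factors):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-14 * max(1.0, np.linalg.norm(X)):
            # residual covariance exhausted: replicate previous coefficients
            for r in range(f, n_factors):
                W[r], P[r], q[r] = 0.0, 0.0, 0.0
                B[r] = b
            return {"W": W, "P": P, "q": q, "SX": SX, "sy": sy, "B": B,
                    "rank_exhausted_at": f}
        w /= nw
        t = X @ w
        tt = float(t @ t)
        pl = X.T @ t / tt
        qf = float(y @ t) / tt
        X -= np.outer(t, pl)
        y = y - qf * t
        a = M @ w
        b = b + g * qf * a
        W[f], P[f], q[f] = w, pl, qf
        B[f] = b
        M = M - np.outer(a, pl)
        if modified:
            sx = X.std(axis=0)
            sx[sx < 1e-12] = 1.0
            syf = y.std()
            if syf < 1e-12:
                syf = 1.0
            X /= sx
            y = y / syf
            M /= sx            # columns of M feed the scaled residual space
            g *= syf
            SX[f] = sx
            sy[f] = syf
    return {"W": W, "P": P, "q": q, "SX": SX, "sy": sy, "B": B,
            "rank_exhausted_at": None}


class MPLS:
    """Modified partial least squares regression model (single response).

    Parameters
    ----------
    endog : array of shape (n,)
        Reference TMQ concentrations, mg g⁻¹ seed.
    exog : array of shape (n, p)
        Processed spectra (rows are samples).
    modified : bool
        Apply the per-factor residual standardization (MPLS).  ``False``
        gives standard PLS1.
    treatment, grid : optional
        Provenance when built via :meth:`from_spectra`; lets results
        predict directly on raw :class:`SpectraSet` inputs.
    """

    def __init__(self, endog, exog, *, modified: bool = True,
                 treatment: MathTreatment | None = None,
                 grid: np.ndarray | None = None,
                 sample_ids=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.size:
            raise ValueError("exog must be (n_samples, n_points) aligned with endog")
        if self.endog.size < 3:
            raise ValueError("MPLS needs at least 3 samples")
        if np.std(self.endog) == 0:
            raise ValueError("degenerate target: reference values are constant")
        self.modified = bool(modified)
        self.treatment = treatment
        self.grid = None if grid is None else np.asarray(grid, dtype=float)
        self.sample_ids = sample_ids
        self.nobs, self.n_points = self.exog.shape

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_spectra(cls, spectra: SpectraSet, treatment: MathTreatment,
                     *, modified: bool = True) -> "MPLS":
        """Apply *treatment* to *spectra* and build the model on the result."""
        if spectra.reference is None:
            raise ValueError("spectra need attached reference TMQ values")
        processed = apply_math_treatment(spectra, treatment)
        return cls(
            processed.reference,
            processed.absorbance,
            modified=modified,
            treatment=treatment,
            grid=processed.wavelengths,
            sample_ids=processed.sample_ids,
        )

    def _max_rank(self) -> int:
        return min(self.nobs - 1, self.n_points)

    def _clip_factors(self, k: int) -> int:
        bound = self._max_rank()
        if k > bound:
            warnings.warn(
                f"max_factors {k} exceeds rank bound {bound}; clipped",
                stacklevel=3,
            )
            return bound
        return k

    # -- estimation -----------------------------------------------------
    def fit(self, n_factors: int) -> "MPLSResults":
        """Extract ``n_factors`` latent factors and return the results."""
        if n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        n_factors = self._clip_factors(n_factors)
        x_mean = self.exog.mean(axis=0)
        y_mean = float(self.endog.mean())
        fac = _nipals_mpls(self.exog - x_mean, self.endog - y_mean,
                           n_factors, self.modified)
        return MPLSResults(self, x_mean, y_mean, n_factors, fac)

    def fit_cv(self, max_factors: int = 16, n_groups: int = 5,
               seed: int = 0, plan: CVPlan | None = None) -> "CVResults":
        """Grouped cross-validation with parsimonious factor selection.

        For each left-out group a model is fitted on the remainder and the
        group predicted at every factor count; SECV(f) pools the
        out-of-group residuals.  The chosen factor count is the smallest f
        whose SECV is within 2% of the minimum (overfitting guard), and the
        returned :attr:`CVResults.results` is the model refitted on all
        samples at that count.
        """
        if plan is None:
            plan = CVPlan(self.nobs, n_groups, seed)
        elif plan.n_samples != self.nobs:
            raise ValueError("plan does not match the number of samples")
        max_factors = self._clip_factors(max_factors)
        # held-out group must leave >= 3 training samples and rank for f
        cv_pred = np.empty((self.nobs, max_factors))
        for _, mask in plan.groups():
            train = ~mask
            sub = MPLS(self.endog[train], self.exog[train],
                       modified=self.modified)
            k = min(max_factors, sub._max_rank())
            res = sub.fit(k)
            pred = res.predict_factorwise(self.exog[mask])  # (m, k)
            if k < max_factors:  # pad with the last available factor count
                pred = np.hstack([pred, np.tile(pred[:, -1:],
                                                max_factors - k)])
            cv_pred[mask] = pred
        residuals = cv_pred - self.endog[:, None]
        secv_curve = np.sqrt(np.mean(residuals**2, axis=0))
        chosen = int(np.argmax(secv_curve <= SECV_PARSIMONY * secv_curve.min())) + 1
        results = self.fit(chosen)
        return CVResults(
            model=self,
            plan=plan,
            secv_curve=secv_curve,
            n_factors_selected=chosen,
            cv_predictions=cv_pred[:, chosen - 1],
            results=results,
        )


class MPLSResults:
    """Fitted MPLS calibration: factors, scales and collapsed coefficients.

    ``params`` is the equivalent linear predictor on processed spectra:
    ``ŷ = intercept + x · params`` reproduces the factor-wise prediction
    path to ~1e-10 (the map is affine, so the collapse is exact up to
    floating point).
    """

    def __init__(self, model: MPLS, x_mean, y_mean, n_factors, factors):
        self.model = model
        self.x_mean = np.asarray(x_mean)
        self.y_mean = float(y_mean)
        self.n_factors = int(n_factors)
        self._fac = factors
        self.params = factors["B"][n_factors - 1]
        self.intercept = self.y_mean - float(self.x_mean @ self.params)
        self.fittedvalues = self.predict(model.exog)
        self.resid = self.fittedvalues - model.endog

    # -- prediction -----------------------------------------------------
    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, SpectraSet):
            if self.model.treatment is None:
                raise ValueError("model was not built from spectra; pass a matrix")
            X = apply_math_treatment(X, self.model.treatment).absorbance
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise GridError(
                f"prediction input has {X.shape[1]} points, model expects "
                f"{self.x_mean.size} (grid mismatch)"
            )
        return X

    def predict(self, X) -> np.ndarray:
        """Predict TMQ for processed spectra (or a raw :class:`SpectraSet`)."""
        X = self._as_matrix(X)
        return self.intercept + X @ self.params

    def predict_factorwise(self, X) -> np.ndarray:
        """Predictions at every factor count 1..n_factors, shape (n, f).

        Replays the stored centering/scaling path factor by factor; the
        final column agrees with :meth:`predict` to ≤1e-8 relative.
        """
        X = self._as_matrix(X)
        fac = self._fac
        out = np.empty((X.shape[0], self.n_factors))
        x_res = X - self.x_mean
        acc = np.full(X.shape[0], self.y_mean)
        g = 1.0
        for f in range(self.n_factors):
            t = x_res @ fac["W"][f]
            acc = acc + g * fac["q"][f] * t
            out[:, f] = acc
            x_res = x_res - np.outer(t, fac["P"][f])
            if self.model.modified:
                x_res = x_res / fac["SX"][f]
                g *= fac["sy"][f]
        return out

    # -- reporting ------------------------------------------------------
    def training_report(self, label: str = "") -> EvaluationReport:
        return summarize(self.model.endog, self.fittedvalues,
                         "calibration", n_factors=self.n_factors, label=label)

    def summary(self) -> str:
        rep = self.training_report()
        lines = [
            "Modified PLS calibration" if self.model.modified
            else "PLS1 calibration",
            f"  samples:        {self.model.nobs}",
            f"  data points:    {self.model.n_points}",
            f"  latent factors: {self.n_factors}",
            f"  SEC:            {rep.se:.3f} mg/g",
            f"  R2:             {rep.r2:.3f}",
            f"  bias:           {float(np.mean(self.resid)):.3e} mg/g",
        ]
        return "\n".join(lines)

    def plot_predictions(self, X=None, reference=None, ax=None):
        """Reference-vs-predicted scatter with the 1:1 line.

        Defaults to the training data; pass a validation set (and its
        reference values when X is a plain matrix) for external plots.
        """
        import matplotlib.pyplot as plt

        if X is None:
            pred, ref = self.fittedvalues, self.model.endog
        else:
            pred = self.predict(X)
            ref = X.reference if isinstance(X, SpectraSet) else reference
            if ref is None:
                raise ValueError("reference values required for the plot")
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(ref, pred, s=12, alpha=0.6)
        lims = [min(ref.min(), pred.min()), max(ref.max(), pred.max())]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel("reference TMQ (mg/g)")
        ax.set_ylabel("predicted TMQ (mg/g)")
        return ax

    # -- serialization --------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "version": SERIALIZATION_VERSION,
            "modified": self.model.modified,
            "n_factors": self.n_factors,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self._fac["W"][: self.n_factors].tolist(),
            "loadings": self._fac["P"][: self.n_factors].tolist(),
            "y_loadings": self._fac["q"][: self.n_factors].tolist(),
            "x_scales": self._fac["SX"][: self.n_factors].tolist(),
            "y_scales": self._fac["sy"][: self.n_factors].tolist(),
            "coefficients": self.params.tolist(),
            "intercept": self.intercept,
            "grid": None if self.model.grid is None else self.model.grid.tolist(),
            "treatment": (None if self.model.treatment is None
                          else self.model.treatment.to_dict()),
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @staticmethod
    def predictor_from_json(source):
        """Load a serialized calibration as a standalone prediction function.

        Accepts a JSON string or a path.  Returns ``(predict, meta)`` where
        ``predict`` maps a processed spectra matrix (or SpectraSet when the
        document carries its treatment) to TMQ values.
        """
        try:
            doc = json.loads(source)
        except (TypeError, json.JSONDecodeError):
            with open(source) as fh:
                doc = json.load(fh)
        if doc.get("version") != SERIALIZATION_VERSION:
            raise ValueError(f"unsupported model document version: "
                             f"{doc.get('version')}")
        coef = np.asarray(doc["coefficients"])
        intercept = float(doc["intercept"])
        treatment = (None if doc["treatment"] is None
                     else MathTreatment.from_dict(doc["treatment"]))

        def predict(X):
            if isinstance(X, SpectraSet):
                if treatment is None:
                    raise ValueError("document has no treatment; pass a matrix")
                X = apply_math_treatment(X, treatment).absorbance
            X = np.atleast_2d(np.asarray(X, dtype=float))
            return intercept + X @ coef

        return predict, doc


@dataclass
class CVResults:
    """Cross-validation outcome: SECV curve, factor choice, CV predictions.

    ``results`` is the final model refitted on all samples at the selected
    factor count; ``cv_predictions`` are the pooled out-of-group
    predictions at that count (the basis of SECV and 1-VR).
    """

    model: MPLS
    plan: CVPlan
    secv_curve: np.ndarray
    n_factors_selected: int
    cv_predictions: np.ndarray
    results: MPLSResults

    @property
    def secv(self) -> float:
        return secv(self.cv_predictions - self.model.endog)

    @property
    def one_minus_vr(self) -> float:
        return one_minus_variance_ratio(self.cv_predictions, self.model.endog)

    def cv_report(self, label: str = "") -> EvaluationReport:
        return summarize(self.model.endog, self.cv_predictions,
                         "cross-validation", label=label)

    def outlier_mask(self, threshold: float = 2.5) -> np.ndarray:
        """Samples whose |CV residual| exceeds ``threshold`` × SECV.

        WinISI-style elimination pass; callers may drop these and refit
        once.  Default analyses leave it off.
        """
        e = self.cv_predictions - self.model.endog
        return np.abs(e) > threshold * self.secv

    def summary(self) -> str:
        lines = [
            self.results.summary(),
            f"  CV groups:      {self.plan.n_groups} (seed {self.plan.seed})",
            f"  SECV:           {self.secv:.3f} mg/g",
            f"  1-VR:           {self.one_minus_vr:.3f}",
        ]
        return "\n".join(lines)
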