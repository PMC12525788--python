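"""Spectral math treatments: SNV, detrend, gap-segment derivative, windowing.

The treatment applied throughout the thymoquinone study is the WinISI-style
tuple (2, 5, 5, 1) — second derivative, gap of 5 data points (10 nm on a
2 nm grid), first smoothing segment of 5 points, no second smoothing —
preceded by standard normal variate (SNV) and detrend scatter correction,
on the 1100–2498 nm window (the visible/short-NIR 400–1100 nm region is
excluded).

Order of operations in :func:`apply_math_treatment` is fixed as
window-restrict → SNV → detrend → derivative.  Edge points whose smoothing
or gap stencil is incomplete are trimmed, never padded: padding fabricates
signal exactly at the window edges where peak analyses read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GridError, SpectraSet

__all__ = [
    "MathTreatment",
    "DegenerateSpectrumError",
    "snv",
    "detrend",
    "gap_segment_derivative",
    "apply_math_treatment",
]


class DegenerateSpectrumError(ValueError):
    """Spectrum is constant (zero variance) and cannot be SNV-scaled."""


@dataclass(frozen=True)
class MathTreatment:
    """Preprocessing recipe.

    Attributes
    ----------
    snv : bool
        Apply standard normal variate (per-spectrum centering/unit-SD).
    detrend : bool
        Subtract a least-squares polynomial in wavelength.
    detrend_order : int
        Polynomial degree for detrend (2 = classic SNV-detrend).
    derivative_order, gap, smooth1, smooth2 : int
        The WinISI ``(d, g, s1, s2)`` tuple, all in data points.  ``smooth2=1``
        means no second smoothing pass.
    window : (float, float) or None
        Wavelength window in nm, inclusive; None keeps the full grid.
    """

    snv: bool = True
    detrend: bool = True
    detrend_order: int = 2
    derivative_order: int = 2
    gap: int = 5
    smooth1: int = 5
    smooth2: int = 1
    window: tuple[float, float] | None = (1100.0, 2498.0)

    def __post_init__(self):
        if self.derivative_order not in (0, 1, 2):
            raise ValueError("derivative order must be 0, 1 or 2")
        if self.gap < 1:
            raise ValueError("gap must be >= 1 data point")
        for name in ("smooth1", "smooth2"):
            s = getattr(self, name)
            if s < 1 or (s != 1 and s % 2 == 0):
                raise ValueError(f"{name} must be 1 or an odd window size")
        if self.detrend_order < 0:
            raise ValueError("detrend order must be >= 0")

    @classmethod
    def identity(cls) -> "MathTreatment":
        return cls(snv=False, detrend=False, derivative_order=0, gap=1,
                   smooth1=1, smooth2=1, window=None)

    def to_dict(self) -> dict:
        return {
            "snv": self.snv,
            "detrend": {"enabled": self.detrend, "order": self.detrend_order},
            "derivative": {
                "d": self.derivative_order,
                "gap": self.gap,
                "smooth1": self.smooth1,
                "smooth2": self.smooth2,
            },
            "window": None if self.window is None else list(self.window),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MathTreatment":
        der = d.get("derivative", {})
        det = d.get("detrend", {})
        if isinstance(det, bool):
            det = {"enabled": det}
        window = d.get("window", (1100.0, 2498.0))
        return cls(
            snv=bool(d.get("snv", True)),
            detrend=bool(det.get("enabled", True)),
            detrend_order=int(det.get("order", 2)),
            derivative_order=int(der.get("d", 2)),
            gap=int(der.get("gap", 5)),
            smooth1=int(der.get("smooth1", 5)),
            smooth2=int(der.get("smooth2", 1)),
            window=None if window is None else tuple(float(v) for v in window),
        )


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: center to mean 0, scale to sample SD 1.

    Removes per-spectrum multiplicative scatter.  Works row-wise on a
    2-D array.  Raises :class:`DegenerateSpectrumError` for a constant
    spectrum.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("SNV needs at least 2 points")
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    # tolerance-based: a numerically constant spectrum leaves SD at rounding level
    if np.any(sd <= 1e-12 * (np.abs(mean) + 1.0)):
        raise DegenerateSpectrumError("constant spectrum has zero SD")
    return (x - mean) / sd


def detrend(x: np.ndarray, grid: np.ndarray, order: int = 2) -> np.ndarray:
    """Residual of a least-squares polynomial fit in wavelength.

    The residual is orthogonal to the polynomial basis; for ``order >= 0``
    its mean is 0 (the intercept is in the basis).
    """
    x = np.asarray(x, dtype=float)
    grid = np.asarray(grid, dtype=float)
    n = grid.size
    if order >= n - 1:
        raise np.linalg.LinAlgError(
            f"detrend order {order} needs more than {order + 1} points, got {n}"
        )
    # Legendre-style scaled basis keeps the Vandermonde well conditioned
    # on nm-scale grids.
    span = np.ptp(grid)
    t = (grid - grid.mean()) / (span / 2 if span else 1.0)
    basis = np.polynomial.polynomial.polyvander(t, order)
    coef, *_ = np.linalg.lstsq(basis, x.T if x.ndim == 2 else x, rcond=None)
    fit = basis @ coef
    return x - (fit.T if x.ndim == 2 else fit)


def _moving_average(x: np.ndarray, s: int) -> tuple[np.ndarray, int]:
    """Centered moving average over ``s`` points; returns (smoothed, trim).

    ``s=1`` is the identity.  The ``(s-1)/2`` edge points on each side,
    where the window is incomplete, are trimmed.
    """
    if s == 1:
        return x, 0
    half = (s - 1) // 2
    if x.shape[-1] < s:
        raise ValueError(f"spectrum of {x.shape[-1]} points shorter than "
                         f"smoothing segment {s}")
    kernel = np.full(s, 1.0 / s)
    if x.ndim == 1:
        sm = np.convolve(x, kernel, mode="valid")
    else:
        sm = np.apply_along_axis(np.convolve, -1, x, kernel, mode="valid")
    return sm, half


def _gap_difference(x: np.ndarray, grid: np.ndarray, gap: int):
    """One application of the centered gap-difference operator.

    First derivative at point i is ``(x[i+h] - x[i-h]) / (2 h Δλ)`` with
    ``h = round(g/2)`` (half-up), i.e. a symmetric stencil scaled by the
    wavelength distance between the stencil points.  Exact for affine and
    (after two applications) quadratic spectra.
    """
    h = int(np.floor(gap / 2 + 0.5))
    if x.shape[-1] < 2 * h + 1:
        raise ValueError(
            f"spectrum of {x.shape[-1]} points too short for gap stencil ±{h}"
        )
    dlam = (grid[1] - grid[0]) * 2 * h
    d = (x[..., 2 * h:] - x[..., : x.shape[-1] - 2 * h]) / dlam
    return d, grid[h : grid.size - h]


def gap_segment_derivative(
    x: np.ndarray,
    grid: np.ndarray,
    d: int,
    gap: int,
    smooth1: int,
    smooth2: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Gap-segment Savitzky-style derivative (WinISI ``(d, g, s1, s2)``).

    Smooths by a centered moving average over ``smooth1`` points, then
    ``smooth2`` points (``1`` = skip), then applies the gap-difference
    operator ``d`` times.  Edges with incomplete stencils are trimmed;
    the surviving wavelength grid is returned alongside the derivative.

    Returns
    -------
    (derivative, grid) : tuple of arrays
    """
    x = np.asarray(x, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if x.shape[-1] != grid.size:
        raise GridError("spectrum and grid lengths differ")
    out, trim = _moving_average(x, smooth1)
    g = grid[trim : grid.size - trim] if trim else grid
    out, trim = _moving_average(out, smooth2)
    g = g[trim : g.size - trim] if trim else g
    for _ in range(d):
        out, g = _gap_difference(out, g, gap)
    return out, g


def apply_math_treatment(spectra: SpectraSet, mt: MathTreatment) -> SpectraSet:
    """Apply a full math treatment to every spectrum of a set.

    Fixed order: window-restrict → SNV → detrend → derivative.  All samples
    are processed identically, so the resulting grid is shared.  Operand
    errors are re-raised with the offending sample_id for context.
    """
    grid = spectra.wavelengths
    X = spectra.absorbance
    if mt.window is not None:
        lo, hi = mt.window
        if lo < grid[0] - 1e-9 or hi > grid[-1] + 1e-9:
            raise GridError(
                f"window [{lo:g}, {hi:g}] nm outside grid "
                f"[{grid[0]:g}, {grid[-1]:g}] nm"
            )
        mask = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
        grid = grid[mask]
        X = X[:, mask]
    try:
        if mt.snv:
            X = snv(X)
        if mt.detrend:
            X = detrend(X, grid, mt.detrend_order)
        X, grid = gap_segment_derivative(
            X, grid, mt.derivative_order, mt.gap, mt.smooth1, mt.smooth2
        )
    except DegenerateSpectrumError:
        # identify the culprit for the error message
        sds = spectra.absorbance.std(axis=1)
        culprit = spectra.sample_ids[np.argmin(sds)]
        raise DegenerateSpectrumError(
            f"constant spectrum (sample_id={culprit!r}) cannot be SNV-scaled"
        ) from None
    return replace_spectra(spectra, X, grid)


def replace_spectra(spectra: SpectraSet, absorbance, grid) -> SpectraSet:
    """New SpectraSet with the same metadata but transformed values/grid."""
    return SpectraSet(
        wavelengths=grid,
        absorbance=absorbance,
        sample_ids=spectra.sample_ids,
        years=spectra.years,
        reference=spectra.reference,
    )
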