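"""Spectra containers and delimited-text I/O.

A :class:`SpectraSet` holds absorbance spectra (log(1/R)) recorded on one
shared, uniformly spaced wavelength grid, together with per-sample metadata
(sample id, harvest year) and, optionally, reference thymoquinone (TMQ)
concentrations in mg per g of seed.

File dialect (CSV, UTF-8): first column ``sample_id``, second column
``year``, optional column ``tmq_mg_per_g``, remaining columns named by
wavelength in nm.  One sample per row.  Missing values inside a spectrum
are not permitted — dense instrument grids are assumed, and imputation
would silently distort derivative spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_GRID",
    "GridError",
    "IdentityError",
    "AlignmentError",
    "SpectraSet",
    "read_spectra",
    "write_spectra",
    "attach_reference",
]

#: Canonical instrument grid: 400–2498 nm inclusive at 2 nm (1050 points).
#: Scanning monochromators of this family emit an even final wavelength.
CANONICAL_GRID = np.arange(400.0, 2500.0, 2.0)

REFERENCE_COLUMN = "tmq_mg_per_g"


class GridError(ValueError):
    """Wavelength grid violates the uniform-spacing / shared-grid contract."""


class IdentityError(ValueError):
    """Duplicate or unknown sample identifiers."""


class AlignmentError(ValueError):
    """Reference values cannot be aligned 1:1 with spectra."""


def _validate_grid(wavelengths: np.ndarray) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise GridError("grid must be a 1-D array of at least 2 wavelengths")
    steps = np.diff(w)
    if np.any(steps <= 0):
        raise GridError("wavelengths must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=0.0, atol=1e-6):
        raise GridError(
            f"non-uniform grid: steps range {steps.min():g}–{steps.max():g} nm"
        )
    return w


@dataclass
class SpectraSet:
    """Ordered collection of spectra on one shared wavelength grid.

    Parameters
    ----------
    wavelengths : array of shape (p,)
        Uniform ascending grid, nm.
    absorbance : array of shape (n, p)
        log(1/R) values, one row per sample; all finite.
    sample_ids : sequence of str
        Unique sample identifiers.
    years : sequence of int
        Harvest-year label per sample.
    reference : array of shape (n,), optional
        TMQ concentration, mg g⁻¹ seed; values ≥ 0.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: np.ndarray
    years: np.ndarray
    reference: np.ndarray | None = None

    def __post_init__(self):
        self.wavelengths = _validate_grid(self.wavelengths)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D (n_samples, n_points) array")
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise GridError(
                f"absorbance has {self.absorbance.shape[1]} columns but the grid "
                f"has {self.wavelengths.size} points"
            )
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.where(~np.isfinite(self.absorbance).all(axis=1))[0]
            raise ValueError(f"non-finite absorbance in rows {bad.tolist()}")
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.years = np.asarray(self.years, dtype=int)
        n = self.absorbance.shape[0]
        if self.sample_ids.size != n or self.years.size != n:
            raise ValueError("sample_ids/years length must match number of spectra")
        ids, counts = np.unique(self.sample_ids, return_counts=True)
        if np.any(counts > 1):
            raise IdentityError(f"duplicate sample_id: {ids[counts > 1].tolist()}")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.shape != (n,):
                raise AlignmentError("reference must align 1:1 with spectra")
            if np.any(self.reference < 0):
                raise ValueError("reference TMQ values must be >= 0")

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.wavelengths.size

    @property
    def grid_step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def subset(self, index) -> "SpectraSet":
        """Row subset by boolean mask or integer indices (order preserved)."""
        idx = np.asarray(index)
        return SpectraSet(
            wavelengths=self.wavelengths,
            absorbance=self.absorbance[idx],
            sample_ids=self.sample_ids[idx],
            years=self.years[idx],
            reference=None if self.reference is None else self.reference[idx],
        )

    def select_years(self, years) -> "SpectraSet":
        years = {int(y) for y in np.atleast_1d(years)}
        mask = np.array([int(y) in years for y in self.years])
        if not mask.any():
            raise ValueError(f"no samples for years {sorted(years)}")
        return self.subset(mask)

    @staticmethod
    def concat(sets: list["SpectraSet"]) -> "SpectraSet":
        """Pool several sets sharing one grid (row order = input order)."""
        if not sets:
            raise ValueError("cannot concatenate an empty list of sets")
        grid = sets[0].wavelengths
        for s in sets[1:]:
            if not np.array_equal(s.wavelengths, grid):
                raise GridError("all pooled sets must share one wavelength grid")
        refs = [s.reference for s in sets]
        if any(r is None for r in refs) and not all(r is None for r in refs):
            raise AlignmentError("cannot pool sets with and without reference values")
        return SpectraSet(
            wavelengths=grid,
            absorbance=np.vstack([s.absorbance for s in sets]),
            sample_ids=np.concatenate([s.sample_ids for s in sets]),
            years=np.concatenate([s.years for s in sets]),
            reference=None if refs[0] is None else np.concatenate(refs),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"sample_id": self.sample_ids, "year": self.years}
        if self.reference is not None:
            cols[REFERENCE_COLUMN] = self.reference
        frame = pd.DataFrame(cols)
        spec = pd.DataFrame(
            self.absorbance, columns=[f"{w:g}" for w in self.wavelengths]
        )
        return pd.concat([frame, spec.set_index(frame.index)], axis=1)


def read_spectra(path, *, expected_step: float = 2.0) -> SpectraSet:
    """Read a spectra CSV into a :class:`SpectraSet`.

    The header declares the wavelengths; rows with non-numeric absorbance
    are rejected with their row index reported.  A grid whose step differs
    from *expected_step* (or is non-uniform) raises :class:`GridError`.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    meta_cols = [c for c in ("sample_id", "year", REFERENCE_COLUMN) if c in df.columns]
    if "sample_id" not in meta_cols or "year" not in meta_cols:
        raise ValueError("file must contain 'sample_id' and 'year' columns")
    wl_cols = [c for c in df.columns if c not in meta_cols]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise GridError(f"non-numeric wavelength column in header: {exc}") from None
    wavelengths = _validate_grid(wavelengths)
    if expected_step is not None and not np.isclose(
        wavelengths[1] - wavelengths[0], expected_step
    ):
        raise GridError(
            f"grid step {wavelengths[1] - wavelengths[0]:g} nm, "
            f"expected {expected_step:g} nm"
        )
    absorbance = df[wl_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    bad_rows = np.where(~np.isfinite(absorbance).all(axis=1))[0]
    if bad_rows.size:
        raise ValueError(
            f"non-numeric or missing absorbance in data rows {bad_rows.tolist()}"
        )
    reference = (
        df[REFERENCE_COLUMN].to_numpy(float) if REFERENCE_COLUMN in df.columns else None
    )
    return SpectraSet(
        wavelengths=wavelengths,
        absorbance=absorbance,
        sample_ids=df["sample_id"].to_numpy(object),
        years=df["year"].to_numpy(int),
        reference=reference,
    )


def write_spectra(spectra: SpectraSet, path) -> None:
    """Write a SpectraSet to CSV; round-trips values to ≤1e-9."""
    if len(spectra) == 0:
        raise ValueError("refusing to write an empty SpectraSet")
    spectra.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_reference_table(path) -> dict[str, float]:
    """Read a sample_id → TMQ (mg g⁻¹) mapping from CSV."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns or REFERENCE_COLUMN not in df.columns:
        raise ValueError(f"reference file needs columns sample_id,{REFERENCE_COLUMN}")
    return dict(zip(df["sample_id"], df[REFERENCE_COLUMN].astype(float)))


def attach_reference(
    spectra: SpectraSet, table: dict[str, float], *, policy: str = "strict"
) -> SpectraSet:
    """Attach reference TMQ values, aligned by sample_id (not row order).

    ``policy='strict'`` raises :class:`AlignmentError` when a sample has no
    table entry; ``policy='drop'`` silently drops such samples.
    """
    if policy not in ("strict", "drop"):
        raise ValueError(f"unknown policy {policy!r}")
    have = np.array([sid in table for sid in spectra.sample_ids])
    if not have.all():
        missing = spectra.sample_ids[~have].tolist()
        if policy == "strict":
            raise AlignmentError(f"no reference value for sample_id {missing}")
        spectra = spectra.subset(have)
    reference = np.array([table[sid] for sid in spectra.sample_ids], dtype=float)
    return SpectraSet(
        wavelengths=spectra.wavelengths,
        absorbance=spectra.absorbance,
        sample_ids=spectra.sample_ids,
        years=spectra.years,
        reference=reference,
    )
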