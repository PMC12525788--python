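"""Significant-wavelength analysis via low/high group-average spectra.

The screening heuristic: average the second-derivative spectra of the 50
lowest-TMQ and the 50 highest-TMQ samples, compute the per-wavelength
standard deviation between the two averages (for two values this is simply
|a − b|/√2), and read the analyte-informative regions off the peaks of
that SD profile.  For thymoquinone the dominant peaks sit near 2106 nm
(C–H bend / C=O stretch combination) and 2254 nm (methylene combination
band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .io import GridError, SpectraSet

__all__ = ["SDProfile", "group_average", "sd_profile", "find_peaks",
           "low_high_groups"]


@dataclass(frozen=True)
class SDProfile:
    """Per-wavelength SD between two group-average spectra."""

    grid: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        if self.grid.shape != self.sd.shape:
            raise GridError("grid and sd must align")
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"wavelength_nm": self.grid, "sd": self.sd})

    def plot(self, ax=None, mark_peaks: int = 2):
        """SD-vs-wavelength line plot with the top peaks annotated."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.sd, lw=0.8)
        if mark_peaks:
            for wl in find_peaks(self, top_k=mark_peaks):
                ax.axvline(wl, color="tab:red", ls="--", lw=0.8)
                ax.annotate(f"{wl:.0f}", (wl, self.sd.max()),
                            ha="center", fontsize=8)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("SD between group averages")
        return ax


def group_average(spectra: SpectraSet, ids) -> np.ndarray:
    """Pointwise mean spectrum over the samples named in *ids*."""
    ids = list(ids)
    if not ids:
        raise ValueError("empty subset")
    id_index = {sid: i for i, sid in enumerate(spectra.sample_ids)}
    missing = [s for s in ids if s not in id_index]
    if missing:
        raise KeyError(f"sample ids not in set: {missing}")
    rows = [id_index[s] for s in ids]
    return spectra.absorbance[rows].mean(axis=0)


def sd_profile(avg_low: np.ndarray, avg_high: np.ndarray,
               grid: np.ndarray) -> SDProfile:
    """Per-wavelength sample SD of the two averages: |a − b|/√2."""
    a = np.asarray(avg_low, dtype=float)
    b = np.asarray(avg_high, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if a.shape != b.shape or a.shape != grid.shape:
        raise GridError("averages and grid must share one shape")
    return SDProfile(grid=grid, sd=np.abs(a - b) / np.sqrt(2.0))


def find_peaks(profile: SDProfile, top_k: int = 2,
               min_separation: float = 20.0) -> list[float]:
    """Local maxima of the SD profile, tallest first.

    Reported peaks are at least *min_separation* nm apart (shoulders of a
    taller peak are suppressed).  A flat profile yields an empty list.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    idx, props = _scipy_find_peaks(profile.sd)
    if idx.size == 0:
        return []
    order = idx[np.argsort(profile.sd[idx])[::-1]]
    chosen: list[float] = []
    for i in order:
        wl = float(profile.grid[i])
        if all(abs(wl - c) >= min_separation for c in chosen):
            chosen.append(wl)
        if len(chosen) == top_k:
            break
    return chosen


def low_high_groups(spectra: SpectraSet, n_low: int = 50,
                    n_high: int = 50) -> tuple[list, list]:
    """Sample ids of the n lowest- and n highest-reference-TMQ samples."""
    if spectra.reference is None:
        raise ValueError("reference TMQ values required to form groups")
    if n_low + n_high > len(spectra):
        raise ValueError("low/high groups exceed the sample count")
    order = np.argsort(spectra.reference, kind="stable")
    low = spectra.sample_ids[order[:n_low]].tolist()
    high = spectra.sample_ids[order[-n_high:]].tolist()
    return low, high
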