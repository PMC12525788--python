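"""Selection predictability: top-fraction overlap between NIRS and HPLC ranks.

In a breeding context the calibration is used to pick the q% of samples
with the highest predicted TMQ.  The match percentage is the share of the
reference-defined (HPLC) top q% that the NIRS-defined top q% captures:
100 × |top_k(pred) ∩ top_k(ref)| / k with k = max(1, round(q·n/100)),
half-up rounding.  An uninformative predictor matches the hypergeometric
expectation 100·k/n on average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SelectionReport", "selection_match", "selection_curve"]


@dataclass(frozen=True)
class SelectionReport:
    """Match outcome at one selection cutoff."""

    cutoff_pct: float
    k: int
    match_pct: float
    n: int
    tie_at_boundary: bool = False

    def __post_init__(self):
        if not 0 <= self.match_pct <= 100:
            raise ValueError("match_pct must be within [0, 100]")


def _top_k_indices(values: np.ndarray, ids: np.ndarray, k: int):
    """Indices of the k largest values; ties broken by sample id.

    Returns (index set, tie_flag) where tie_flag marks a tie crossing the
    k-th rank boundary (the choice then depends on the id tie-break).
    """
    # descending by value, ascending by id among equals
    order = np.lexsort((ids, -values))
    top = order[:k]
    tie = bool(k < values.size and values[order[k - 1]] == values[order[k]])
    return set(top.tolist()), tie


def selection_match(predicted, reference, cutoff_pct, ids=None) -> SelectionReport:
    """Fraction of the reference top-q% captured by the predicted top-q%.

    ``k = max(1, round(q·n/100))`` (half-up).  Ties at the k-th rank are
    resolved deterministically by sample id and flagged in the report.
    """
    pred = np.asarray(predicted, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float).ravel()
    if pred.size != ref.size or pred.size == 0:
        raise ValueError("predicted and reference must be aligned, non-empty")
    if not 0 < cutoff_pct < 100:
        raise ValueError("cutoff must be in (0, 100) percent")
    n = pred.size
    if ids is None:
        ids = np.arange(n)
    else:
        ids = np.asarray(ids)
    k = max(1, int(np.floor(cutoff_pct * n / 100 + 0.5)))
    top_pred, tie_p = _top_k_indices(pred, ids, k)
    top_ref, tie_r = _top_k_indices(ref, ids, k)
    match = 100.0 * len(top_pred & top_ref) / k
    return SelectionReport(
        cutoff_pct=float(cutoff_pct),
        k=k,
        match_pct=match,
        n=n,
        tie_at_boundary=tie_p or tie_r,
    )


def selection_curve(predicted, reference, cutoffs=(5, 10, 15),
                    ids=None) -> list[SelectionReport]:
    """One independent :func:`selection_match` report per cutoff."""
    return [selection_match(predicted, reference, c, ids=ids) for c in cutoffs]
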