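"""Rank utilities shared by the CMC and profiling modules."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

#: relative gap below which two scores are considered numerically tied
TIE_RTOL = 1e-9


def snap_ties(x: np.ndarray, rtol: float = TIE_RTOL) -> np.ndarray:
    """Merge score values separated by floating-point jitter.

    Nodes that are exchangeable under a graph automorphism receive
    mathematically identical scores on every centrality measure, but
    eigensolvers and matrix exponentials return them with jitter in the
    last bits, which would break exact rank ties.  Sorted values whose
    successive gaps fall below ``rtol * max|x|`` are merged to their group
    mean before ranking.
    """
    x = np.asarray(x, dtype=float)
    scale = np.max(np.abs(x)) if x.size else 0.0
    if scale == 0.0:
        return x.copy()
    tol = rtol * scale
    order = np.argsort(x, kind="stable")
    xs = x[order]
    new_group = np.empty(len(xs), dtype=bool)
    new_group[0] = True
    new_group[1:] = np.diff(xs) > tol
    group = np.cumsum(new_group) - 1
    sums = np.bincount(group, weights=xs)
    counts = np.bincount(group)
    snapped_sorted = (sums / counts)[group]
    out = np.empty_like(xs)
    out[order] = snapped_sorted
    return out


def tied_ranks(x: np.ndarray, rtol: float = TIE_RTOL) -> np.ndarray:
    """Average ranks after numerical tie-snapping."""
    return rankdata(snap_ties(x, rtol), method="average")
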