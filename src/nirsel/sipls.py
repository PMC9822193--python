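"""Synergy interval PLS (SIPLS) wavelength-interval selection.

The retained spectrum is cut into n equidistant contiguous intervals
(n scanned over a range, default 10..30); every combination of
``n_combine`` (default 4) intervals is scored by the leave-one-out
RMSECV of a PLS1 model on the concatenated columns.  The per-n best
combination is tabulated and the global winner is the minimum-RMSECV
combination over the whole scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .pls import loocv_select_lv
from .subset import VariableSubset

__all__ = ["IntervalScheme", "make_intervals", "sipls_search"]


@dataclass(frozen=True)
class IntervalScheme:
    """Contiguous half-open index intervals partitioning [0, p)."""

    n_intervals: int
    boundaries: tuple  # of (start, end) pairs

    def indices(self, k: int) -> np.ndarray:
        s, e = self.boundaries[k]
        return np.arange(s, e)


def make_intervals(p: int, n_intervals: int) -> IntervalScheme:
    """Split p variables into n nearly equal contiguous intervals.

    Base length floor(p/n); the first p mod n intervals get one extra
    variable, so lengths differ by at most 1.
    """
    if n_intervals < 2:
        raise ValueError("need at least 2 intervals")
    if n_intervals > p:
        raise ValueError("more intervals than variables")
    base, rem = divmod(p, n_intervals)
    bounds = []
    start = 0
    for k in range(n_intervals):
        length = base + (1 if k < rem else 0)
        bounds.append((start, start + length))
        start += length
    assert start == p
    return IntervalScheme(n_intervals=n_intervals, boundaries=tuple(bounds))


def sipls_search(X, y, n_intervals_range=range(10, 31), n_combine: int = 4,
                 max_lv: int = 10):
    """Exhaustive interval-combination search -> (winner, scan table).

    The table has one row per interval count: NI, NV, LVs, Rcv, RMSECV,
    RPDCV of that count's best combination.  The global winner is the
    minimum-RMSECV combination across all counts; ties break toward
    fewer variables, then the lexicographically smallest combination.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    p = X.shape[1]
    counts = list(n_intervals_range)
    if not counts:
        raise ValueError("empty interval-count range")
    if n_combine > min(counts):
        raise ValueError("n_combine exceeds the smallest interval count")
    rows = []
    best = None  # (rmsecv, nv, combo, n_int, cv)
    for n_int in counts:
        scheme = make_intervals(p, n_int)
        best_n = None
        for combo in combinations(range(n_int), n_combine):
            cols = np.concatenate([scheme.indices(k) for k in combo])
            cv = loocv_select_lv(X[:, cols], y, max_lv=max_lv)
            key = (cv.rmsecv, len(cols), combo)
            if best_n is None or key < best_n[0]:
                best_n = (key, cols, cv)
        (rmse, nv, combo), cols, cv = best_n
        rows.append({"NI": n_int, "NV": nv, "LVs": cv.chosen_lv,
                     "Rcv": cv.rcv, "RMSECV": rmse, "RPDCV": cv.rpdcv,
                     "combination": combo})
        if best is None or (rmse, nv, combo) < best[0]:
            best = ((rmse, nv, combo), n_int, cols, cv)
    (rmse, nv, combo), n_int, cols, cv = best
    winner = VariableSubset(
        indices=np.sort(cols), method="sipls", rmsecv=rmse,
        n_lv=cv.chosen_lv,
        hyperparameters={"n_intervals": n_int, "combination": list(combo),
                         "n_combine": n_combine, "max_lv": max_lv},
    )
    return winner, pd.DataFrame(rows)
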