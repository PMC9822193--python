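"""Competitive adaptive reweighted sampling (CARS) wavelength selection.

Over ``n_runs`` Monte Carlo samplings (default 100), each run fits a
PLS1 model on a random fraction of the samples using the currently
retained variables, then shrinks the variable set in two stages:

1. *Forced removal* — keep the round(r_i * p) variables with the
   largest absolute regression coefficients, where the retention ratio
   r_i follows an exponentially decreasing function (EDF) pinned to
   keep all p variables at the first run and 2 at the last.
2. *Adaptive reweighted sampling (ARS)* — sample that many variables
   with replacement with probability proportional to |b|; the retained
   set is the set of unique draws (competitive survival).

Every run's retained set is scored by cross-validated RMSECV on all
samples; the output subset is the retained set of the best run,
re-scored by leave-one-out CV for comparability with other selectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pls import cv_rmse, fit_pls, loocv_select_lv
from .subset import VariableSubset

__all__ = ["CARSTrace", "edf_schedule", "cars_select"]


@dataclass
class CARSTrace:
    retained_count: np.ndarray
    rmsecv: np.ndarray
    retained_indices: list
    best_iteration: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "run": np.arange(1, len(self.rmsecv) + 1),
            "retained_count": self.retained_count,
            "rmsecv": self.rmsecv,
        })


def edf_schedule(p: int, n_runs: int, terminal: float = 2.0) -> np.ndarray:
    """Retention ratios r_i = a*exp(-k*i), i = 1..n_runs.

    Boundary conditions r_1 * p = p and r_N * p = ``terminal`` give the
    closed forms a = (p/terminal)^(1/(N-1)), k = ln(p/terminal)/(N-1).
    """
    if p < 2 or n_runs < 2:
        raise ValueError("need p >= 2 and n_runs >= 2")
    ratio = p / terminal
    a = ratio ** (1.0 / (n_runs - 1))
    k = np.log(ratio) / (n_runs - 1)
    i = np.arange(1, n_runs + 1)
    return a * np.exp(-k * i)


def cars_select(X, y, n_runs: int = 100, calib_fraction: float = 0.8,
                cv_folds: int = 5, max_lv: int = 10, seed: int = 0):
    """Run CARS -> (VariableSubset, CARSTrace)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    rng = np.random.default_rng(seed)
    ratios = edf_schedule(p, n_runs)
    n_cal = max(2, int(round(calib_fraction * n)))
    retained = np.arange(p)
    counts, scores, sets = [], [], []
    for i in range(n_runs):
        cal = rng.choice(n, size=n_cal, replace=False)
        lv = min(max_lv, n_cal - 1, len(retained))
        model = fit_pls(X[np.ix_(cal, retained)], y[cal], n_lv=lv)
        absb = np.abs(model.b)
        n_keep = max(2, int(round(ratios[i] * p)))
        n_keep = min(n_keep, len(retained))
        # forced removal: largest |b| survive (stable order for ties)
        order = np.argsort(-absb, kind="stable")
        forced = retained[order[:n_keep]]
        w = absb[order[:n_keep]]
        if n_keep == len(retained) and n_keep == p:
            # first run: the EDF keeps everything, so there is nothing
            # for the competitive resampling to decide yet
            retained = np.sort(forced)
        elif w.sum() <= 0:
            retained = np.sort(forced)
        else:
            # p draws (original variable count) with replacement, so the
            # competitive pruning concentrates on the low-|b| tail and
            # the retained counts track the EDF
            draws = rng.choice(len(forced), size=p, replace=True,
                               p=w / w.sum())
            retained = np.sort(forced[np.unique(draws)])
        if len(retained) < 2:
            break
        counts.append(len(retained))
        scores.append(cv_rmse(X[:, retained], y, n_folds=cv_folds,
                              max_lv=min(max_lv, len(retained)),
                              seed=seed + 7919 * (i + 1)))
        sets.append(retained.copy())
    if not sets:
        raise RuntimeError("variable set collapsed before any run completed")
    best = int(np.argmin(scores))
    trace = CARSTrace(
        retained_count=np.array(counts), rmsecv=np.array(scores),
        retained_indices=sets, best_iteration=best)
    final = sets[best]
    cv = loocv_select_lv(X[:, final], y, max_lv=min(max_lv, len(final)))
    subset = VariableSubset(
        indices=final, method="cars", rmsecv=cv.rmsecv, n_lv=cv.chosen_lv,
        hyperparameters={"n_runs": n_runs, "calib_fraction": calib_fraction,
                         "cv_folds": cv_folds, "max_lv": max_lv,
                         "seed": seed, "best_run": best + 1},
    )
    return subset, trace
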