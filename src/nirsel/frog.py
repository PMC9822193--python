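"""Random frog: trans-dimensional subset sampling for variable ranking.

A reversible-jump-flavoured chain over variable subsets: from the
current subset V of size Q a candidate dimension Q* is drawn from
N(Q, variance_factor*Q); the candidate subset grows by recruiting the
strongest variables from a random pool (ranked by |b| of a PLS fit) or
shrinks by dropping the weakest members of V.  A candidate with a
better cross-validated RMSECV is accepted outright, a worse one with
probability accept_factor * RMSECV(V)/RMSECV(V*).  The per-variable
selection frequency over the chain estimates each variable's selection
probability; a nested top-k refinement (default sizes 500, 460, ... by
steps of 40) then picks the best prefix by leave-one-out RMSECV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pls import cv_rmse, fit_pls, loocv_select_lv
from .subset import VariableSubset

__all__ = ["FrogTrace", "frog_probabilities", "frog_refine"]

#: candidate pool size = _POOL_FACTOR * (Q* - Q) when growing
_POOL_FACTOR = 3


@dataclass
class FrogTrace:
    selection_count: np.ndarray
    n_iterations: int
    hyperparameters: dict

    @property
    def probability(self) -> np.ndarray:
        return self.selection_count / self.n_iterations

    def as_frame(self, wavenumbers=None) -> pd.DataFrame:
        out = pd.DataFrame({"variable": np.arange(len(self.selection_count)),
                            "probability": self.probability})
        if wavenumbers is not None:
            out.insert(1, "wavenumber", np.asarray(wavenumbers))
        return out


def _fit_absb(X, y, cols, max_lv):
    lv = min(max_lv, len(cols), X.shape[0] - 1)
    model = fit_pls(X[:, cols], y, n_lv=lv)
    return np.abs(model.b)


def frog_probabilities(X, y, n_iter: int = 10_000, Q_init: int = 2,
                       variance_factor: float = 0.3,
                       accept_factor: float = 0.1, max_lv: int = 10,
                       cv_folds: int = 5, seed: int = 0) -> FrogTrace:
    """Run the chain and return per-variable selection counts."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 variables")
    if not 1 <= Q_init <= p:
        raise ValueError("Q_init out of range")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    V = np.sort(rng.choice(p, size=Q_init, replace=False))
    counts = np.zeros(p, dtype=np.int64)

    def score(cols, tag):
        return cv_rmse(X[:, cols], y, n_folds=cv_folds,
                       max_lv=min(max_lv, len(cols)), seed=seed ^ tag)

    rmse_V = score(V, 0)
    for it in range(n_iter):
        counts[V] += 1  # count the subset held at this iteration
        Q = len(V)
        Q_star = int(np.clip(round(rng.normal(Q, variance_factor * Q)), 1, p))
        if Q_star > Q:
            outside = np.setdiff1d(np.arange(p), V, assume_unique=False)
            n_add = Q_star - Q
            pool = rng.choice(outside,
                              size=min(len(outside), _POOL_FACTOR * n_add),
                              replace=False)
            union = np.concatenate([V, pool])
            absb = _fit_absb(X, y, union, max_lv)
            keep = np.argsort(-absb, kind="stable")[:Q_star]
            V_star = np.sort(union[keep])
        elif Q_star < Q:
            absb = _fit_absb(X, y, V, max_lv)
            keep = np.argsort(-absb, kind="stable")[:Q_star]
            V_star = np.sort(V[keep])
        else:
            V_star = V
        if V_star is V:
            rmse_star = rmse_V
        else:
            rmse_star = score(V_star, it + 1)
        if rmse_star <= rmse_V or \
                rng.random() < accept_factor * (rmse_V / rmse_star):
            V, rmse_V = V_star, rmse_star
    return FrogTrace(
        selection_count=counts, n_iterations=n_iter,
        hyperparameters={"Q_init": Q_init, "variance_factor": variance_factor,
                         "accept_factor": accept_factor, "max_lv": max_lv,
                         "cv_folds": cv_folds, "seed": seed})


def frog_refine(X, y, trace: FrogTrace, top_n: int = 500, step: int = 40,
                max_lv: int = 10):
    """Evaluate nested top-probability prefixes -> best VariableSubset.

    Variables are ranked by selection probability (ties toward the
    smaller index); subsets of sizes top_n, top_n - step, ... down to
    the smallest positive size are scored by leave-one-out RMSECV.
    Returns (winner, curve) where curve tabulates (n_variables, RMSECV).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    p = X.shape[1]
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    top_n = min(top_n, p)
    prob = trace.probability
    # descending probability, ascending index on ties
    rank = np.lexsort((np.arange(p), -prob))
    sizes = list(range(top_n, 0, -step))
    rows, best = [], None
    for size in sizes:
        cols = np.sort(rank[:size])
        cv = loocv_select_lv(X[:, cols], y, max_lv=min(max_lv, size))
        rows.append({"n_variables": size, "LVs": cv.chosen_lv,
                     "RMSECV": cv.rmsecv})
        if best is None or cv.rmsecv < best[0]:
            best = (cv.rmsecv, size, cols, cv)
    rmse, size, cols, cv = best
    winner = VariableSubset(
        indices=cols, method="random_frog", rmsecv=rmse, n_lv=cv.chosen_lv,
        hyperparameters={"top_n": top_n, "step": step, "max_lv": max_lv,
                         **trace.hyperparameters})
    return winner, pd.DataFrame(rows)
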