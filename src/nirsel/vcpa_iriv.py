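"""VCPA pre-compression followed by IRIV classification and backward
elimination.

Variable combination population analysis (VCPA) shrinks the variable
space along an exponentially decreasing schedule.  Each loop draws a
population of random sub-models by binary matrix sampling (BMS), scores
every sub-model by cross-validated RMSECV, and scores every variable by
its frequency among the best 15% of models minus its frequency among
the worst 5%; the highest-scoring variables survive the shrink.  The
compressed set (default 100 variables) is handed to IRIV, which
classifies each variable by the paired effect of flipping it out of the
sub-models that contain it (mean RMSECV difference + rank-sum test):
strongly/weakly informative variables are kept, uninformative and
interfering ones deleted, iterating until no deletions remain.  A
greedy backward elimination then removes variables whose deletion
lowers the leave-one-out RMSECV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .cars import edf_schedule
from .pls import cv_rmse, loocv_select_lv
from .subset import VariableSubset

__all__ = [
    "BMSMatrix", "IRIVClassification", "bms_sample", "vcpa_reduce",
    "iriv_classify", "iriv_iterate", "backward_eliminate",
    "vcpa_iriv_select",
]


@dataclass
class BMSMatrix:
    """Binary inclusion matrix (K sub-models x p variables)."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if not np.isin(m, (0, 1)).all():
            raise ValueError("BMS matrix entries must be 0/1")
        if (m.sum(axis=1) < 2).any():
            raise ValueError("every BMS row needs at least 2 ones")
        self.matrix = m.astype(bool)

    @property
    def inclusion_ratio(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


@dataclass
class IRIVClassification:
    dmean: np.ndarray     # mean(RMSECV excluded) - mean(RMSECV included)
    p_value: np.ndarray
    classes: np.ndarray   # 'strong' | 'weak' | 'uninformative' | 'interfering'

    def as_frame(self, wavenumbers=None) -> pd.DataFrame:
        out = pd.DataFrame({"dmean": self.dmean, "p_value": self.p_value,
                            "class": self.classes})
        if wavenumbers is not None:
            out.insert(0, "wavenumber", np.asarray(wavenumbers))
        return out


def bms_sample(p: int, K: int, inclusion_ratio: float = 0.5,
               seed: int = 0) -> BMSMatrix:
    """Independent Bernoulli inclusion matrix; rows with < 2 ones redrawn."""
    if not 0.0 < inclusion_ratio < 1.0:
        raise ValueError("inclusion_ratio must be in (0, 1)")
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    m = rng.random((K, p)) < inclusion_ratio
    while True:
        bad = np.flatnonzero(m.sum(axis=1) < 2)
        if len(bad) == 0:
            break
        m[bad] = rng.random((len(bad), p)) < inclusion_ratio
    return BMSMatrix(matrix=m)


def _score_rows(X, y, bms: BMSMatrix, cols, cv_folds, max_lv, seed):
    """Cross-validated RMSECV of each BMS row's sub-model."""
    scores = np.empty(bms.matrix.shape[0])
    for k, row in enumerate(bms.matrix):
        sel = cols[row]
        scores[k] = cv_rmse(X[:, sel], y, n_folds=cv_folds,
                            max_lv=min(max_lv, len(sel)),
                            seed=seed + 31 * k)
    return scores


def vcpa_reduce(X, y, target_count: int = 100, n_edf_loops: int = 5,
                K: int = 1000, best_frac: float = 0.15,
                worst_frac: float = 0.05, inclusion_ratio: float = 0.5,
                cv_folds: int = 5, max_lv: int = 10,
                seed: int = 0):
    """EDF-scheduled shrinkage by best-vs-worst sub-model frequencies.

    Returns (indices, score_table) where score_table records the first
    loop's per-variable frequency score (the plotted analog of the
    best/worst frequency histogram).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    p = X.shape[1]
    if target_count >= p:
        raise ValueError("target_count must be smaller than p")
    sizes = np.maximum(
        np.round(edf_schedule(p, n_edf_loops + 1, terminal=target_count) * p
                 ).astype(int)[1:], target_count)
    sizes[-1] = target_count
    cols = np.arange(p)
    first_scores = None
    for loop, new_size in enumerate(sizes):
        bms = bms_sample(len(cols), K, inclusion_ratio,
                         seed=seed + 1009 * loop)
        scores = _score_rows(X, y, bms, cols, cv_folds, max_lv,
                             seed=seed + 1009 * loop + 1)
        order = np.argsort(scores, kind="stable")
        n_best = max(1, int(round(best_frac * K)))
        n_worst = max(1, int(round(worst_frac * K)))
        f_best = bms.matrix[order[:n_best]].mean(axis=0)
        f_worst = bms.matrix[order[-n_worst:]].mean(axis=0)
        var_score = f_best - f_worst
        if first_scores is None:
            first_scores = pd.DataFrame({
                "variable": cols, "f_best": f_best, "f_worst": f_worst,
                "score": var_score})
        keep = np.argsort(-var_score, kind="stable")[:new_size]
        cols = np.sort(cols[keep])
    return cols, first_scores


def iriv_classify(X, y, variables, K: int = 200,
                  inclusion_ratio: float = 0.5, alpha: float = 0.05,
                  cv_folds: int = 5, max_lv: int = 10,
                  seed: int = 0) -> IRIVClassification:
    """Classify variables by their inclusion/exclusion effect on RMSECV.

    For variable i, the sub-models (BMS rows) containing i are refit
    with i flipped out; dmean_i = mean(excluded) - mean(included) over
    those paired models, and the two-sided Mann-Whitney rank-sum test
    compares the two RMSECV populations.  Classes: strong (dmean > 0,
    p < alpha), weak (dmean > 0, p >= alpha), uninformative (dmean <= 0,
    p >= alpha), interfering (dmean <= 0, p < alpha).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    cols = np.asarray(variables, dtype=int)
    pp = len(cols)
    if pp < 3:
        raise ValueError("need at least 3 variables")
    bms = bms_sample(pp, K, inclusion_ratio, seed=seed)
    base = _score_rows(X, y, bms, cols, cv_folds, max_lv, seed=seed + 1)
    dmean = np.empty(pp)
    pval = np.empty(pp)
    for i in range(pp):
        rows = np.flatnonzero(bms.matrix[:, i])
        usable = rows[bms.matrix[rows].sum(axis=1) >= 3]  # flip leaves >= 2
        if len(usable) < 3:
            raise ValueError(
                f"variable {cols[i]} appears in too few sub-models "
                f"(K too small for the rank test)")
        r_in = base[usable]
        r_out = np.empty(len(usable))
        for j, k in enumerate(usable):
            sel = cols[bms.matrix[k] & (np.arange(pp) != i)]
            r_out[j] = cv_rmse(X[:, sel], y, n_folds=cv_folds,
                               max_lv=min(max_lv, len(sel)),
                               seed=seed + 1 + 31 * k)
        dmean[i] = r_out.mean() - r_in.mean()
        if np.allclose(r_out, r_in):
            pval[i] = 1.0
        else:
            pval[i] = mannwhitneyu(r_out, r_in,
                                   alternative="two-sided").pvalue
    informative = dmean > 0
    significant = pval < alpha
    classes = np.where(
        informative, np.where(significant, "strong", "weak"),
        np.where(significant, "interfering", "uninformative"))
    return IRIVClassification(dmean=dmean, p_value=pval, classes=classes)


def iriv_iterate(X, y, variables, K: int = 200, inclusion_ratio: float = 0.5,
                 alpha: float = 0.05, cv_folds: int = 5, max_lv: int = 10,
                 seed: int = 0):
    """Delete uninformative + interfering variables until stable.

    Returns (surviving indices, per-round summary DataFrame).
    """
    cols = np.asarray(variables, dtype=int)
    rounds = []
    for rnd in range(len(cols)):
        cls = iriv_classify(X, y, cols, K=K, inclusion_ratio=inclusion_ratio,
                            alpha=alpha, cv_folds=cv_folds, max_lv=max_lv,
                            seed=seed + 7001 * rnd)
        keep = np.isin(cls.classes, ("strong", "weak"))
        rounds.append({
            "round": rnd + 1, "n_in": len(cols),
            "n_strong": int((cls.classes == "strong").sum()),
            "n_weak": int((cls.classes == "weak").sum()),
            "n_removed": int((~keep).sum())})
        if keep.all():
            break
        if not keep.any():
            raise ValueError("IRIV removed every variable; review alpha/K")
        cols = cols[keep]
        if len(cols) < 3:
            break
    return cols, pd.DataFrame(rounds)


def backward_eliminate(X, y, variables, max_lv: int = 10) -> VariableSubset:
    """Greedy removal of single variables while LOO RMSECV improves.

    At each step every remaining variable's removal is evaluated; the
    single removal that most decreases RMSECV is executed (ties toward
    the smallest index); the loop stops when every removal strictly
    worsens the error.  A removal that leaves the error unchanged (to
    floating tolerance, e.g. a perfectly collinear duplicate) counts as
    acceptable: parsimony wins ties.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    cols = np.asarray(variables, dtype=int)
    if len(cols) < 2:
        raise ValueError("need at least 2 variables")
    cv = loocv_select_lv(X[:, cols], y, max_lv=min(max_lv, len(cols)))
    current = cv.rmsecv
    chosen_cv = cv
    while len(cols) > 2:
        best = None
        for i in range(len(cols)):
            trial = np.delete(cols, i)
            tcv = loocv_select_lv(X[:, trial], y,
                                  max_lv=min(max_lv, len(trial)))
            if tcv.rmsecv <= current * (1 + 1e-10) and \
                    (best is None or tcv.rmsecv < best[0]):
                best = (tcv.rmsecv, i, trial, tcv)
        if best is None:
            break
        current, _, cols, chosen_cv = best
    return VariableSubset(
        indices=cols, method="vcpa_iriv_backward", rmsecv=current,
        n_lv=chosen_cv.chosen_lv, hyperparameters={"max_lv": max_lv})


def vcpa_iriv_select(X, y, target_count: int = 100, n_edf_loops: int = 5,
                     K_vcpa: int = 1000, K_iriv: int = 200,
                     best_frac: float = 0.15, worst_frac: float = 0.05,
                     inclusion_ratio: float = 0.5, alpha: float = 0.05,
                     cv_folds: int = 5, max_lv: int = 10, seed: int = 0):
    """Full VCPA -> IRIV -> backward elimination chain.

    Returns (VariableSubset, artifacts dict with the VCPA frequency
    table, IRIV round summary and final classification inputs).
    """
    reduced, freq = vcpa_reduce(
        X, y, target_count=target_count, n_edf_loops=n_edf_loops, K=K_vcpa,
        best_frac=best_frac, worst_frac=worst_frac,
        inclusion_ratio=inclusion_ratio, cv_folds=cv_folds, max_lv=max_lv,
        seed=seed)
    survivors, rounds = iriv_iterate(
        X, y, reduced, K=K_iriv, inclusion_ratio=inclusion_ratio,
        alpha=alpha, cv_folds=cv_folds, max_lv=max_lv, seed=seed + 17)
    subset = backward_eliminate(X, y, survivors, max_lv=max_lv)
    subset.method = "vcpa_iriv"
    subset.hyperparameters.update({
        "target_count": target_count, "n_edf_loops": n_edf_loops,
        "K_vcpa": K_vcpa, "K_iriv": K_iriv, "best_frac": best_frac,
        "worst_frac": worst_frac, "alpha": alpha, "seed": seed})
    return subset, {"vcpa_frequencies": freq, "iriv_rounds": rounds,
                    "reduced": reduced, "survivors": survivors}
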