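"""Monte Carlo cross-validation (MCCV) outlier screening.

Samples are repeatedly split at random (default 75:25, 1000 times); a
PLS1 model fit on each calibration part predicts the held-out part, and
absolute prediction residuals are accumulated per sample.  Samples
whose residual mean or spread sits far from the bulk are flagged:
either against user-supplied absolute cutoffs, or (default) a robust
median + 5*MAD fence on each statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pls import fit_pls, loocv_select_lv, predict

__all__ = ["OutlierReport", "mccv_residuals", "flag_outliers",
           "combine_flags"]


@dataclass
class OutlierReport:
    """Per-sample absolute-residual statistics from the MCCV loop.

    ``sd_residual`` uses denominator (k-1) for k >= 2 hold-out
    occurrences and is 0 for k = 1; samples never held out carry NaN
    statistics (and a warning is emitted).
    """

    mean_residual: np.ndarray
    sd_residual: np.ndarray
    n_times_in_prediction_set: np.ndarray
    params: dict

    def as_frame(self, sample_ids=None) -> pd.DataFrame:
        n = len(self.mean_residual)
        return pd.DataFrame({
            "sample_id": sample_ids if sample_ids is not None else range(n),
            "mean_residual": self.mean_residual,
            "sd_residual": self.sd_residual,
            "n_held_out": self.n_times_in_prediction_set,
        })


def mccv_residuals(X, y, n_iter: int = 1000, split_ratio: float = 0.75,
                   max_lv: int = 10, lv: int | None = None,
                   seed: int = 0) -> OutlierReport:
    """Accumulate absolute hold-out residuals over random splits.

    The component count is chosen once by leave-one-out CV on the full
    data and then held fixed for every Monte Carlo refit (pass ``lv``
    to override).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0.0 < split_ratio < 1.0:
        raise ValueError("split_ratio must be in (0, 1)")
    if lv is None:
        lv = loocv_select_lv(X, y, max_lv=max_lv).chosen_lv
    n_cal = int(np.floor(split_ratio * n))
    if n_cal < 2 or n_cal >= n:
        raise ValueError("split ratio leaves a degenerate partition")
    rng = np.random.default_rng(seed)
    s = np.zeros(n)
    s2 = np.zeros(n)
    k = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        perm = rng.permutation(n)
        cal, pred = perm[:n_cal], perm[n_cal:]
        model = fit_pls(X[cal], y[cal], n_lv=min(lv, n_cal - 1))
        r = np.abs(predict(model, X[pred]) - y[pred])
        s[pred] += r
        s2[pred] += r * r
        k[pred] += 1
    never = k == 0
    if never.any():
        warnings.warn(f"{never.sum()} sample(s) never held out after "
                      f"{n_iter} iterations; statistics undefined for them")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(never, np.nan, s / np.maximum(k, 1))
        var = (s2 - k * mean ** 2) / np.maximum(k - 1, 1)
        sd = np.where(never, np.nan, np.sqrt(np.maximum(var, 0.0)))
        sd = np.where(k == 1, 0.0, sd)
    return OutlierReport(
        mean_residual=mean, sd_residual=sd, n_times_in_prediction_set=k,
        params={"n_iter": n_iter, "split_ratio": split_ratio,
                "lv": int(lv), "seed": seed})


def _robust_fence(x: np.ndarray, k: float) -> float:
    # MAD as the normal-consistent scale estimator (x 1.4826), the
    # convention of median +/- k*MAD outlier fences
    x = x[np.isfinite(x)]
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    return med + k * mad


def flag_outliers(report: OutlierReport, mode: str = "robust",
                  mean_cut: float | None = None,
                  sd_cut: float | None = None,
                  connective: str = "or",
                  mad_factor: float = 5.0) -> set:
    """Flag suspicious samples from an MCCV residual report.

    ``absolute`` mode applies user-given cutoffs on the mean and SD,
    combined by the given AND/OR connective.  ``robust`` mode (default)
    flags samples whose mean or SD exceeds median + ``mad_factor``*MAD
    of that statistic, which needs no data-scale knowledge.
    """
    mean, sd = report.mean_residual, report.sd_residual
    if mode == "absolute":
        if mean_cut is None or sd_cut is None:
            raise ValueError("absolute mode requires mean_cut and sd_cut")
        hit_m = mean > mean_cut
        hit_s = sd > sd_cut
        if connective == "and":
            hits = hit_m & hit_s
        elif connective == "or":
            hits = hit_m | hit_s
        else:
            raise ValueError(f"unknown connective {connective!r}")
    elif mode == "robust":
        hits = (mean > _robust_fence(mean, mad_factor)) | \
               (sd > _robust_fence(sd, mad_factor))  # either statistic
    else:
        raise ValueError(f"unknown mode {mode!r}")
    hits &= np.isfinite(mean)
    return set(np.flatnonzero(hits).tolist())


def combine_flags(per_analyte_flags: dict, how: str = "intersection") -> set:
    """Merge per-analyte flag sets into the final removal set.

    Default ``intersection``: only samples flagged for *every* analyte
    are removed (a sample flagged by a single assay alone is kept, as
    in screening on the common extremes of both indicators);
    ``union`` removes a sample flagged for at least one analyte.
    """
    sets = list(per_analyte_flags.values())
    if not sets:
        return set()
    if how == "union":
        return set().union(*sets)
    if how == "intersection":
        out = set(sets[0])
        for s in sets[1:]:
            out &= s
        return out
    raise ValueError(f"unknown combination rule {how!r}")
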