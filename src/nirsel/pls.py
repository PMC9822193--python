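"""PLS1 regression, latent-variable selection and calibration metrics.

The calibration model throughout the package is single-response partial
least squares (PLS1) computed by NIPALS on mean-centered data.  For a
single response the NIPALS component is non-iterative: the weight vector
of each component is proportional to the covariance X'y of the deflated
predictor block with the (centered) response, which makes leave-one-out
cross-validation over a grid of component counts cheap enough to use as
the universal model-scoring rule.

Metric conventions (all checked against each other in the test suite):

* RMSE uses denominator ``n`` (population mean square).
* R is the Pearson correlation between reference and predicted values.
* RSE, in percent, is RMSE normalised by the root mean square of the
  reference values: ``100 * sqrt(sum((yhat-y)^2) / sum(y^2))``, which
  equals ``100 * RMSE / sqrt(mean(y)^2 + popvar(y))``.
* RPD is the population standard deviation (denominator ``n``) of the
  reference values divided by RMSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "CVResult",
    "EvaluationReport",
    "fit_pls",
    "predict",
    "loocv_select_lv",
    "cv_rmse",
    "metric_rmse",
    "metric_r",
    "metric_rse",
    "metric_rpd",
    "rse_from_moments",
    "rpd_from_moments",
    "evaluate",
]


@dataclass
class PLSModel:
    """A fitted mean-centered NIPALS PLS1 model.

    ``b`` is the regression vector on the original (centered) variable
    scale, so predictions are ``y_mean + (x - x_mean) @ b``.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray        # (n_lv, p) normalised weight vectors
    x_loadings: np.ndarray     # (n_lv, p)
    y_loadings: np.ndarray     # (n_lv,)
    b: np.ndarray              # (p,)
    n_lv: int
    variable_indices: np.ndarray | None = None

    def __post_init__(self):
        if self.n_lv < 1:
            raise ValueError("n_lv must be >= 1")


@dataclass
class CVResult:
    rmsecv_per_lv: np.ndarray
    chosen_lv: int
    rcv: float
    rpdcv: float
    loo_predictions: np.ndarray = field(default=None, repr=False)

    @property
    def rmsecv(self) -> float:
        return float(self.rmsecv_per_lv[self.chosen_lv - 1])


@dataclass
class EvaluationReport:
    rc: float
    rmsec: float
    rsec: float
    rpdc: float
    rp: float
    rmsep: float
    rsep: float
    rpdp: float

    def as_dict(self) -> dict:
        return {
            "Rc": self.rc, "RMSEC": self.rmsec, "RSEC": self.rsec,
            "RPDC": self.rpdc, "Rp": self.rp, "RMSEP": self.rmsep,
            "RSEP": self.rsep, "RPDP": self.rpdp,
        }


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """Run NIPALS PLS1 on centered data; returns (W, P, Q, B_per_lv).

    ``B_per_lv[a]`` is the regression vector using components 1..a+1,
    built incrementally from the relation R = W (P'W)^-1 via
    r_a = w_a - sum_{j<a} (p_j . w_a) r_j.
    """
    n, p = Xc.shape
    W = np.empty((n_lv, p))
    P = np.empty((n_lv, p))
    Q = np.empty(n_lv)
    R = np.empty((n_lv, p))
    B = np.empty((n_lv, p))
    X = Xc.copy()
    y = yc.copy()
    b = np.zeros(p)
    actual = 0
    for a in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < 1e-28:
            break
        pa = (X.T @ t) / tt
        qa = (y @ t) / tt
        X -= np.outer(t, pa)
        y = y - qa * t
        W[a], P[a], Q[a] = w, pa, qa
        r = w - R[:a].T @ (P[:a] @ w) if a else w.copy()
        R[a] = r
        b = b + qa * r
        B[a] = b
        actual = a + 1
    return W[:actual], P[:actual], Q[:actual], B[:actual]


def fit_pls(X, y, n_lv: int, variable_indices=None) -> PLSModel:
    """Fit a mean-centered NIPALS PLS1 model with ``n_lv`` components.

    ``n_lv`` is truncated (with a warning) if it exceeds
    ``min(n_samples - 1, n_variables)`` or the effective rank of X.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y have incompatible lengths")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    cap = min(n - 1, p)
    if n_lv > cap:
        warnings.warn(f"n_lv={n_lv} exceeds min(n-1, p)={cap}; truncated")
        n_lv = cap
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, Q, B = _nipals_pls1(X - x_mean, y - y_mean, n_lv)
    if len(Q) < n_lv:
        warnings.warn(f"rank deficiency: only {len(Q)} components extracted")
    if len(Q) == 0:
        raise ValueError("no PLS component could be extracted")
    return PLSModel(
        x_mean=x_mean, y_mean=y_mean, weights=W, x_loadings=P,
        y_loadings=Q, b=B[-1], n_lv=len(Q),
        variable_indices=None if variable_indices is None
        else np.asarray(variable_indices),
    )


def predict(model: PLSModel, X_new) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.b.shape[0]:
        raise ValueError(
            f"model was fit on {model.b.shape[0]} variables, "
            f"got {X_new.shape[1]}")
    return model.y_mean + (X_new - model.x_mean) @ model.b


def _loo_prediction_matrix(X, y, max_lv: int) -> np.ndarray:
    """(n, max_lv) matrix of leave-one-out predictions per component count."""
    n, p = X.shape
    preds = np.full((n, max_lv), np.nan)
    idx = np.arange(n)
    for i in range(n):
        m = idx != i
        Xt, yt = X[m], y[m]
        cap = min(max_lv, len(yt) - 1, p)
        xm = Xt.mean(axis=0)
        ym = yt.mean()
        _, _, _, B = _nipals_pls1(Xt - xm, yt - ym, cap)
        xc = X[i] - xm
        k = B.shape[0]
        if k:
            preds[i, :k] = ym + B @ xc
        if k < max_lv:  # rank-limited: extend with last available model
            preds[i, k:] = preds[i, k - 1] if k else ym
    return preds


def loocv_select_lv(X, y, max_lv: int = 10) -> CVResult:
    """Choose the component count by leave-one-out cross-validation.

    RMSECV is computed for 1..max_lv components; the chosen count is the
    first minimum.  Rcv is the Pearson correlation between the reference
    values and the pooled LOO predictions at the chosen count, and RPDCV
    is the population SD of y divided by RMSECV.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if max_lv >= n:
        warnings.warn(f"max_lv={max_lv} >= n={n}; capped at n-1")
        max_lv = n - 1
    max_lv = min(max_lv, p)
    preds = _loo_prediction_matrix(X, y, max_lv)
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    chosen = int(np.argmin(rmsecv)) + 1
    yhat = preds[:, chosen - 1]
    return CVResult(
        rmsecv_per_lv=rmsecv,
        chosen_lv=chosen,
        rcv=metric_r(y, yhat),
        rpdcv=float(np.std(y) / rmsecv[chosen - 1]),
        loo_predictions=preds,
    )


def cv_rmse(X, y, n_folds: int, max_lv: int = 10, seed: int = 0) -> float:
    """K-fold cross-validated RMSE at the best component count <= max_lv.

    Folds are assigned by dealing the y-sorted samples round-robin, so
    every fold spans the response range (seed rotates the dealing
    order).  Used as the cheap inner scorer of the Monte Carlo
    selectors; final subsets are re-scored by LOO for comparability.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    n_folds = min(n_folds, n)
    order = np.argsort(y, kind="stable")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = (np.arange(n) + rng.integers(n_folds)) % n_folds
    max_lv = min(max_lv, p)
    preds = np.full((n, max_lv), np.nan)
    for f in range(n_folds):
        m = fold_of != f
        Xt, yt = X[m], y[m]
        cap = min(max_lv, len(yt) - 1, p)
        xm = Xt.mean(axis=0)
        ym = yt.mean()
        _, _, _, B = _nipals_pls1(Xt - xm, yt - ym, cap)
        Xv = X[~m] - xm
        k = B.shape[0]
        if k:
            preds[~m, :k] = ym + Xv @ B.T
        if k < max_lv:
            preds[~m, k:] = preds[~m, k - 1][:, None] if k else ym
    rmse = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    return float(np.min(rmse))


# ---------------------------------------------------------------- metrics

def metric_rmse(y, yhat) -> float:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if len(y) != len(yhat):
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def metric_r(y, yhat) -> float:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValueError("zero-variance reference values")
    if np.ptp(yhat) == 0:
        return 0.0
    return float(np.corrcoef(y, yhat)[0, 1])


def metric_rse(y, yhat) -> float:
    """Relative standard error in percent: 100*sqrt(SSE / sum(y^2))."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    return float(100.0 * np.sqrt(np.sum((yhat - y) ** 2) / np.sum(y ** 2)))


def metric_rpd(y, rmse: float) -> float:
    """Population SD of y (denominator n) divided by RMSE."""
    y = np.asarray(y, dtype=float).ravel()
    sd = float(np.std(y))
    if sd == 0:
        raise ValueError("zero-variance reference values")
    return sd / rmse


def rse_from_moments(rmse: float, mean: float, sd: float, n: int) -> float:
    """RSE (%) from summary statistics of the reference values.

    ``sd`` is the sample standard deviation (denominator n-1), as
    reported in summary tables; it is converted to the population SD
    before applying RSE = RMSE / sqrt(mean^2 + popvar).
    """
    popvar = sd ** 2 * (n - 1) / n
    return float(100.0 * rmse / np.sqrt(mean ** 2 + popvar))


def rpd_from_moments(rmse: float, sd: float, n: int) -> float:
    """RPD from the sample SD of the reference values."""
    return float(sd * np.sqrt((n - 1) / n) / rmse)


def evaluate(model: PLSModel, X_cal, y_cal, X_pred, y_pred) -> EvaluationReport:
    """External validation: the full metric suite on both sample sets."""
    yc_hat = predict(model, X_cal)
    yp_hat = predict(model, X_pred)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    rmsec = metric_rmse(y_cal, yc_hat)
    rmsep = metric_rmse(y_pred, yp_hat)
    return EvaluationReport(
        rc=metric_r(y_cal, yc_hat),
        rmsec=rmsec,
        rsec=metric_rse(y_cal, yc_hat),
        rpdc=metric_rpd(y_cal, rmsec),
        rp=metric_r(y_pred, yp_hat),
        rmsep=rmsep,
        rsep=metric_rse(y_pred, yp_hat),
        rpdp=metric_rpd(y_pred, rmsep),
    )
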