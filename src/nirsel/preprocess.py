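"""Spectral pretreatments and the screening harness that ranks them.

Four pretreatments are compared: row normalization, standard normal
variate (SNV), multiplicative scatter correction (MSC) and
Savitzky-Golay smoothing (derivative order 0).  All are row-local
except MSC's default reference (the column-mean spectrum) and none
change the matrix shape.  The screen ranks configurations by
leave-one-out RMSECV of a PLS1 model built on the treated matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .pls import loocv_select_lv

__all__ = [
    "PretreatmentConfig", "sg_smooth", "snv", "msc", "normalize",
    "apply_pretreatment", "pretreatment_screen",
]

_METHODS = ("raw", "normalization", "snv", "msc", "sg_smoothing")
_NORM_MODES = ("max_abs", "vector_norm", "area")


@dataclass(frozen=True)
class PretreatmentConfig:
    method: str = "raw"
    sg_window: int = 11
    sg_polyorder: int = 2
    normalization_mode: str = "max_abs"
    label: str = field(default=None)

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "sg_smoothing":
            if self.sg_window % 2 == 0:
                raise ValueError("sg_window must be odd")
            if self.sg_window < self.sg_polyorder + 2:
                raise ValueError("require sg_window >= sg_polyorder + 2")
        if self.normalization_mode not in _NORM_MODES:
            raise ValueError(f"unknown normalization mode "
                             f"{self.normalization_mode!r}")
        if self.label is None:
            object.__setattr__(self, "label", self.method)


def sg_smooth(X, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay least-squares smoothing along each row.

    Edges are handled by evaluating the polynomial fitted to the
    truncated terminal window, so a row sampled from a polynomial of
    degree <= ``polyorder`` is reproduced exactly everywhere.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > X.shape[1]:
        raise ValueError("window exceeds the number of variables")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    return savgol_filter(X, window, polyorder, axis=1, mode="interp")


def snv(X) -> np.ndarray:
    """Standard normal variate: center and scale each row (SD with n-1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if len(bad):
        raise ValueError(f"constant row(s) {bad.tolist()}: SNV undefined")
    return (X - mu) / sd


def msc(X, reference=None) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed as x = a + b*reference (ordinary least
    squares); the corrected row is (x - a) / b.  The reference defaults
    to the column-mean spectrum of X.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.shape[0] != X.shape[1]:
        raise ValueError("reference length mismatch")
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom == 0:
        raise ValueError("constant reference spectrum")
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(np.abs(b) < 1e-12):
        raise ValueError("degenerate MSC fit (|b| ~ 0) for some row")
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None]


def normalize(X, mode: str = "max_abs") -> np.ndarray:
    """Row normalization: max_abs, vector_norm (L2) or area (L1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if mode == "max_abs":
        d = np.abs(X).max(axis=1)
    elif mode == "vector_norm":
        d = np.linalg.norm(X, axis=1)
    elif mode == "area":
        d = np.abs(X).sum(axis=1)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if np.any(d == 0):
        raise ValueError("all-zero row cannot be normalized")
    return X / d[:, None]


def apply_pretreatment(X, cfg: PretreatmentConfig) -> np.ndarray:
    if cfg.method == "raw":
        return np.asarray(X, dtype=float).copy()
    if cfg.method == "normalization":
        return normalize(X, cfg.normalization_mode)
    if cfg.method == "snv":
        return snv(X)
    if cfg.method == "msc":
        return msc(X)
    if cfg.method == "sg_smoothing":
        return sg_smooth(X, cfg.sg_window, cfg.sg_polyorder)
    raise ValueError(f"unknown method {cfg.method!r}")


def pretreatment_screen(X, y, configs, max_lv: int = 10) -> pd.DataFrame:
    """Rank pretreatments by LOO RMSECV of the resulting PLS1 model.

    Returns one row per configuration (Pretreatment, LVs, Rcv, RMSECV,
    RPDCV) in input order plus a boolean ``winner`` column marking the
    minimum-RMSECV row (first on ties).
    """
    configs = list(configs)
    if not configs:
        raise ValueError("no pretreatment configurations given")
    rows = []
    for cfg in configs:
        cv = loocv_select_lv(apply_pretreatment(X, cfg), y, max_lv=max_lv)
        rows.append({"Pretreatment": cfg.label, "LVs": cv.chosen_lv,
                     "Rcv": cv.rcv, "RMSECV": cv.rmsecv, "RPDCV": cv.rpdcv})
    table = pd.DataFrame(rows)
    table["winner"] = False
    table.loc[table["RMSECV"].idxmin(), "winner"] = True
    return table
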