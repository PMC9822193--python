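"""SPXY sample-set partitioning (joint x-y distance Kennard-Stone).

The calibration set is grown greedily on a joint distance that weights
spectral and reference space equally:

    d(i, j) = dx(i, j) / max(dx) + dy(i, j) / max(dy)

starting from the most mutually distant pair and repeatedly adding the
sample whose minimum distance to the current calibration set is
largest.  The procedure is fully deterministic; ties break toward the
smallest sample index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SplitResult", "joint_distance_matrix", "spxy_split"]


@dataclass
class SplitResult:
    calibration_indices: np.ndarray
    prediction_indices: np.ndarray
    ratio: float

    def __post_init__(self):
        c = set(self.calibration_indices.tolist())
        p = set(self.prediction_indices.tolist())
        if c & p:
            raise ValueError("calibration and prediction sets overlap")


def joint_distance_matrix(X, y) -> np.ndarray:
    """Symmetric zero-diagonal matrix of max-normalized x + y distances.

    Euclidean distance in both blocks; a block whose maximum distance
    is zero (all samples identical there) contributes 0.  Every entry
    is therefore <= 2, with equality iff a pair attains both maxima.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if len(y) != X.shape[0]:
        raise ValueError("X and y are not aligned")
    dx = cdist(X, X)
    dy = cdist(y, y)
    d = np.zeros_like(dx)
    if dx.max() > 0:
        d += dx / dx.max()
    if dy.max() > 0:
        d += dy / dy.max()
    return d


def spxy_split(X, y, ratio: float = 0.75) -> SplitResult:
    """Deterministic SPXY split with |calibration| = floor(ratio * n)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    if n < 3:
        raise ValueError("need at least 3 samples")
    n_cal = int(np.floor(ratio * n))
    if n_cal < 2:
        raise ValueError("ratio leaves fewer than 2 calibration samples")
    d = joint_distance_matrix(X, y)
    # seed: first (row-major, i.e. smallest-index) pair attaining max d
    i, j = np.unravel_index(np.argmax(d), d.shape)
    selected = [min(i, j), max(i, j)]
    in_cal = np.zeros(n, dtype=bool)
    in_cal[selected] = True
    # min distance of every sample to the current calibration set
    min_d = d[:, selected].min(axis=1)
    while in_cal.sum() < n_cal:
        min_d_masked = np.where(in_cal, -np.inf, min_d)
        nxt = int(np.argmax(min_d_masked))  # argmax -> smallest index on ties
        in_cal[nxt] = True
        min_d = np.minimum(min_d, d[:, nxt])
    return SplitResult(
        calibration_indices=np.flatnonzero(in_cal),
        prediction_indices=np.flatnonzero(~in_cal),
        ratio=ratio,
    )
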