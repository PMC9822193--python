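"""Provenance-carrying variable subsets returned by every selector."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VariableSubset"]


@dataclass
class VariableSubset:
    """Retained variable (column) indices plus how they were obtained.

    ``indices`` refer to columns of the matrix the selector ran on;
    ``wavenumbers`` (when known) carry the corresponding grid values.
    ``rmsecv`` is the achieved leave-one-out RMSECV of the subset.
    """

    indices: np.ndarray
    method: str
    rmsecv: float
    n_lv: int
    hyperparameters: dict = field(default_factory=dict)
    wavenumbers: np.ndarray | None = None

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) == 0:
            raise ValueError("empty variable subset")

    def __len__(self):
        return len(self.indices)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "indices": self.indices.tolist(),
            "wavenumbers": None if self.wavenumbers is None
            else np.asarray(self.wavenumbers).tolist(),
            "rmsecv": self.rmsecv,
            "n_lv": self.n_lv,
            "hyperparameters": {k: (v.tolist() if isinstance(v, np.ndarray)
                                    else v)
                                for k, v in self.hyperparameters.items()},
        }
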