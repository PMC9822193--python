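"""Spectral dataset container, CSV round-tripping and grid operations.

A dataset couples an absorbance matrix (samples x wavenumbers) with a
strictly descending wavenumber grid in the 12,000-4,000 cm^-1 NIR
region, per-sample metadata (sample_id, batch_id, time_min) and an
optional table of reference concentrations (mg/mL) per analyte.

The on-disk dialect is plain comma-delimited UTF-8 text: the spectra
file has the three metadata columns followed by one column per
wavenumber (header printed with enough digits for a lossless
round-trip); the reference file is wide, keyed by sample_id with one
column per analyte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GRID_MIN", "GRID_MAX",
    "WavenumberGrid", "SpectralDataset", "ExclusionInterval",
    "read_dataset", "write_dataset", "average_replicates", "exclude_region",
]

GRID_MIN = 4000.0
GRID_MAX = 12000.0

_META_COLS = ["sample_id", "batch_id", "time_min"]


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly descending wavenumber axis (cm^-1) within [4000, 12000]."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or len(v) < 2:
            raise ValueError("grid needs at least 2 wavenumbers")
        if not np.all(np.diff(v) < 0):
            raise ValueError("wavenumber grid must be strictly decreasing")
        if v.min() < GRID_MIN - 1e-9 or v.max() > GRID_MAX + 1e-9:
            raise ValueError("wavenumbers outside the 4,000-12,000 cm^-1 region")

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class ExclusionInterval:
    """Closed wavenumber interval [low, high] to drop (e.g. a saturated band)."""

    high: float
    low: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("require low < high")


@dataclass
class SpectralDataset:
    absorbance: np.ndarray
    grid: WavenumberGrid
    sample_meta: pd.DataFrame
    references: pd.DataFrame | None = None
    # provenance of column selections: retained index -> index in the
    # original full grid (identity when nothing was excluded)
    column_origin: np.ndarray = field(default=None)

    def __post_init__(self):
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be 2-D (samples x wavenumbers)")
        n, p = self.absorbance.shape
        if p != len(self.grid):
            raise ValueError("column count does not match grid length")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if len(self.sample_meta) != n:
            raise ValueError("sample_meta row count does not match n_samples")
        missing = [c for c in _META_COLS if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample_meta missing columns {missing}")
        if self.references is not None and len(self.references) != n:
            raise ValueError("references do not align 1:1 with samples")
        if self.column_origin is None:
            self.column_origin = np.arange(p)

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_variables(self) -> int:
        return self.absorbance.shape[1]

    def subset_samples(self, indices) -> "SpectralDataset":
        indices = np.asarray(indices)
        return SpectralDataset(
            absorbance=self.absorbance[indices],
            grid=self.grid,
            sample_meta=self.sample_meta.iloc[indices].reset_index(drop=True),
            references=None if self.references is None
            else self.references.iloc[indices].reset_index(drop=True),
            column_origin=self.column_origin.copy(),
        )


def read_dataset(spectra_path, reference_path=None) -> SpectralDataset:
    """Read a spectra CSV (and optional reference CSV joined on sample_id)."""
    df = pd.read_csv(spectra_path)
    if list(df.columns[:3]) != _META_COLS:
        raise ValueError(
            f"spectra file must start with columns {_META_COLS}, "
            f"got {list(df.columns[:3])}")
    try:
        wavenumbers = np.array([float(c) for c in df.columns[3:]])
    except ValueError as e:
        raise ValueError(f"non-numeric wavenumber in header: {e}") from e
    grid = WavenumberGrid(wavenumbers)  # raises on ascending/duplicate axes
    body = df.iloc[:, 3:]
    bad = body.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        r, c = np.argwhere(bad.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric absorbance at row {r} (sample "
            f"{df['sample_id'].iloc[r]!r}), column {df.columns[3 + c]!r}")
    refs = None
    if reference_path is not None:
        rdf = pd.read_csv(reference_path)
        if "sample_id" not in rdf.columns:
            raise ValueError("reference file must have a sample_id column")
        rdf = rdf.set_index("sample_id")
        missing = [s for s in df["sample_id"] if s not in rdf.index]
        if missing:
            raise ValueError(
                f"sample_id mismatch: {missing[:5]} absent from reference file")
        refs = rdf.loc[df["sample_id"]].reset_index(drop=True)
    return SpectralDataset(
        absorbance=bad.to_numpy(dtype=float),
        grid=grid,
        sample_meta=df[_META_COLS].copy(),
        references=refs,
    )


def write_dataset(ds: SpectralDataset, spectra_path, reference_path=None):
    """Write the CSV pair; values printed at 10 significant digits."""
    header = [f"{v:.10g}" for v in ds.grid.values]
    out = pd.concat(
        [ds.sample_meta.reset_index(drop=True),
         pd.DataFrame(ds.absorbance, columns=header)], axis=1)
    out.to_csv(spectra_path, index=False, float_format="%.10g")
    if reference_path is not None and ds.references is not None:
        ref = ds.references.copy()
        ref.insert(0, "sample_id", ds.sample_meta["sample_id"].to_numpy())
        ref.to_csv(reference_path, index=False, float_format="%.10g")


def average_replicates(ds: SpectralDataset, group_key: str = "sample_id"
                       ) -> SpectralDataset:
    """Collapse replicate rows to their mean spectrum, one row per group.

    Metadata (and references) of the first member of each group are
    retained; group order follows first appearance.
    """
    if group_key not in ds.sample_meta.columns:
        raise ValueError(f"unknown group key {group_key!r}")
    keys = ds.sample_meta[group_key]
    first_rows, mean_rows = [], []
    for _, idx in keys.groupby(keys, sort=False).groups.items():
        pos = ds.sample_meta.index.get_indexer(idx)
        first_rows.append(pos[0])
        mean_rows.append(ds.absorbance[pos].mean(axis=0))
    return SpectralDataset(
        absorbance=np.vstack(mean_rows),
        grid=ds.grid,
        sample_meta=ds.sample_meta.iloc[first_rows].reset_index(drop=True),
        references=None if ds.references is None
        else ds.references.iloc[first_rows].reset_index(drop=True),
        column_origin=ds.column_origin.copy(),
    )


def exclude_region(ds: SpectralDataset, interval: ExclusionInterval
                   ) -> SpectralDataset:
    """Drop every grid point in the closed interval [low, high].

    Column order is otherwise preserved and the retained->original index
    mapping is composed into ``column_origin``.  Idempotent for a fixed
    interval.
    """
    v = ds.grid.values
    keep = ~((v >= interval.low) & (v <= interval.high))
    if keep.sum() < 2:
        raise ValueError("exclusion would leave fewer than 2 variables")
    if keep.all():
        return replace(ds)
    return SpectralDataset(
        absorbance=ds.absorbance[:, keep],
        grid=WavenumberGrid(v[keep]),
        sample_meta=ds.sample_meta.copy(),
        references=None if ds.references is None else ds.references.copy(),
        column_origin=ds.column_origin[keep],
    )
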