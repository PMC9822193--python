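"""Synthetic alcohol-precipitation NIR datasets with known ground truth.

The generator emulates in-line transmission NIR monitoring of an
alcohol-precipitation (ethanol addition) step: an aqueous herbal extract
is progressively diluted, so the two monitored marker compounds follow
correlated, monotonically declining concentration profiles.  Spectra
are built from a Beer-Lambert mixture model:

    A(s, nu) = m_s * [ sum_a c_{s,a} * pure_a(nu) + solvent(nu) ]
               + o_s + g_s * nu_scaled + eps_s(nu)

with Gaussian absorption bands for the pure components, a fixed solvent
background whose strong O-H combination band saturates (hard-clips) on
5235-5078 cm^-1, per-sample multiplicative scatter m_s ~ N(1, sd),
additive offset o_s and baseline tilt g_s, and heteroscedastic white
noise whose SD is elevated below 4413 cm^-1 (detector roll-off region).

Concentration profiles use a shared-denominator dilution model per
batch, c(t) = c0 * V0 / (V0 + r (t - t0)): both analytes in a batch are
divided by the same growing volume, which is what makes their profiles
strongly correlated across samples.  Batch endpoints vary (150-170 min),
mimicking batch-to-batch fluctuation of the process.

Every sampled quantity is driven by one seeded generator, so a fixed
seed reproduces the dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import ExclusionInterval, SpectralDataset, WavenumberGrid

__all__ = [
    "AnalyteSpec", "SimulationConfig", "GroundTruth",
    "DEFAULT_ANALYTES", "SATURATED_REGION",
    "build_full_grid", "pure_spectrum", "concentration_profiles",
    "simulate_dataset", "plant_outliers",
]

#: Saturated solvent O-H combination band removed before any modeling.
SATURATED_REGION = ExclusionInterval(high=5235.0, low=5078.0)

#: Number of grid points: a uniform 2072-point axis over 12,000-4,000
#: cm^-1 (spacing ~3.863 cm^-1, half the 8 cm^-1 instrument resolution)
#: leaves exactly 2032 variables once the saturated region is excluded.
N_GRID_POINTS = 2072


@dataclass(frozen=True)
class AnalyteSpec:
    """Pure-component model: Gaussian bands + admissible concentration range.

    ``bands`` is a list of (center cm^-1, width cm^-1, height in
    absorbance units per mg/mL) tuples.
    """

    name: str
    bands: tuple
    concentration_range: tuple

    def __post_init__(self):
        for c, w, h in self.bands:
            if w <= 0 or h <= 0:
                raise ValueError("band widths and heights must be positive")
            if not (4000.0 <= c <= 12000.0):
                raise ValueError("band center outside the grid span")
        lo, hi = self.concentration_range
        if not lo < hi:
            raise ValueError("concentration_range must satisfy min < max")


# Band layouts follow the marker compounds' chemistry: both are
# polyhydroxy compounds (O-H overtones above 10,000 and combinations at
# 5000-4000 cm^-1); the glycoside's C-H overtones sit near 7600/6000
# cm^-1 while the flavonoid's aromatic C-H moves to ~6500 cm^-1.
DEFAULT_ANALYTES = (
    AnalyteSpec(
        name="geniposide",
        bands=((10400.0, 260.0, 0.012), (7600.0, 180.0, 0.010),
               (6000.0, 220.0, 0.011), (4300.0, 140.0, 0.013)),
        concentration_range=(2.74, 7.82),
    ),
    AnalyteSpec(
        name="baicalin",
        bands=((10200.0, 260.0, 0.015), (6500.0, 200.0, 0.014),
               (4400.0, 150.0, 0.016)),
        concentration_range=(1.76, 4.72),
    ),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of the generator.

    Defaults reproduce the monitored campaign: 6 batches sampled every
    10 min starting at t = 90 min with batch durations drawn in
    [150, 170] min, topped up with extra samples to 101 in total, and
    2 planted outlier samples.
    """

    n_batches: int = 6
    t_start_min: float = 90.0
    t_interval_min: float = 10.0
    batch_duration_range: tuple = (150.0, 170.0)
    n_total_samples: int = 101
    noise_sd_base: float = 0.001
    noise_sd_low_wn_region: float = 0.005
    low_wn_threshold: float = 4413.0
    scatter_slope_sd: float = 0.01
    offset_sd: float = 0.005
    tilt_sd: float = 0.002
    concentration_jitter_sigma: float = 0.005
    n_outliers: int = 2
    outlier_mode: str = "concentration_shift"
    outlier_shift_mg_per_ml: float = 1.0
    saturation_ceiling: float = 2.5
    seed: int = 0

    def __post_init__(self):
        for name in ("noise_sd_base", "noise_sd_low_wn_region",
                     "scatter_slope_sd", "offset_sd", "tilt_sd",
                     "concentration_jitter_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.outlier_mode not in ("concentration_shift", "spectral_artifact"):
            raise ValueError(f"unknown outlier_mode {self.outlier_mode!r}")


@dataclass
class GroundTruth:
    """What the generator knows and downstream stages must recover."""

    true_concentrations: pd.DataFrame       # n_samples x analytes (mg/mL)
    informative_variable_indices: dict      # analyte -> full-grid indices
    outlier_indices: np.ndarray
    batch_params: pd.DataFrame = field(default=None)


def build_full_grid() -> WavenumberGrid:
    """The instrument's uniform descending axis, 12,000 -> 4,000 cm^-1."""
    return WavenumberGrid(np.linspace(12000.0, 4000.0, N_GRID_POINTS))


def pure_spectrum(analyte: AnalyteSpec, grid: WavenumberGrid) -> np.ndarray:
    """Unit-concentration absorbance of one analyte on the grid."""
    nu = grid.values
    s = np.zeros_like(nu)
    for c, w, h in analyte.bands:
        s += h * np.exp(-0.5 * ((nu - c) / w) ** 2)
    return s


def _solvent_spectrum(grid: WavenumberGrid) -> np.ndarray:
    """Aqueous-ethanol background (pre-detector, unclipped).

    The O-H combination band near 5160 cm^-1 is tall and broad enough
    that clipping the *measured* signal at the detector ceiling
    produces a flat saturated plateau covering the whole 5235-5078
    cm^-1 exclusion window for any realistic per-sample scatter; the
    hydrogen-bonded O-H band spans 7680-7540 cm^-1.
    """
    nu = grid.values
    return (0.55 * np.exp(-0.5 * ((nu - 7610.0) / 70.0) ** 2)   # 7680-7540
            + 6.0 * np.exp(-0.5 * ((nu - 5160.0) / 80.0) ** 2)  # saturating
            + 0.25 * np.exp(-0.5 * ((nu - 6900.0) / 350.0) ** 2)  # water
            + 0.05)


def _sample_schedule(cfg: SimulationConfig, rng: np.random.Generator):
    """(batch_id, time_min) rows: regular batch sampling plus extras."""
    durations = rng.uniform(*cfg.batch_duration_range, size=cfg.n_batches)
    rows = []
    for b in range(cfg.n_batches):
        t = cfg.t_start_min
        while t <= durations[b] + 1e-9:
            rows.append((b, t))
            t += cfg.t_interval_min
    n_extra = cfg.n_total_samples - len(rows)
    if n_extra < 0:
        raise ValueError("n_total_samples smaller than scheduled batch samples")
    for _ in range(n_extra):
        b = int(rng.integers(cfg.n_batches))
        rows.append((b, float(rng.uniform(cfg.t_start_min, durations[b]))))
    return rows, durations


def concentration_profiles(cfg: SimulationConfig,
                           analytes=DEFAULT_ANALYTES,
                           rng: np.random.Generator | None = None,
                           schedule=None) -> GroundTruth:
    """Generate correlated declining concentration profiles per batch.

    Both analytes in a batch share the dilution denominator
    V0 + r (t - t0); starting concentrations c0 are drawn near the top
    of each analyte's admissible range; multiplicative lognormal jitter
    models assay error; values are clipped to the admissible range.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if schedule is None:
        schedule, _ = _sample_schedule(cfg, rng)
    batch_ids = np.array([b for b, _ in schedule])
    times = np.array([t for _, t in schedule])
    # dilution rate (1/min): by batch end the volume roughly doubles to
    # triples, so concentrations sweep most of the admissible range
    rates = rng.uniform(0.013, 0.023, size=cfg.n_batches)
    c0 = {}
    for a in analytes:
        lo, hi = a.concentration_range
        # start in the top ~12% of the range so the full dilution stays in range
        c0[a.name] = rng.uniform(hi - 0.12 * (hi - lo), hi, size=cfg.n_batches)
    denom = 1.0 + rates[batch_ids] * (times - cfg.t_start_min)
    conc = {}
    for a in analytes:
        c = c0[a.name][batch_ids] / denom
        jitter = np.exp(rng.normal(0.0, cfg.concentration_jitter_sigma,
                                   size=len(c)))
        conc[a.name] = np.clip(c * jitter, *a.concentration_range)
    return GroundTruth(
        true_concentrations=pd.DataFrame(conc),
        informative_variable_indices={},
        outlier_indices=np.array([], dtype=int),
        batch_params=pd.DataFrame(
            {"batch_id": np.arange(cfg.n_batches), "rate": rates}),
    )


def simulate_dataset(cfg: SimulationConfig = SimulationConfig(),
                     analytes=DEFAULT_ANALYTES):
    """Full forward simulation -> (SpectralDataset, GroundTruth)."""
    rng = np.random.default_rng(cfg.seed)
    grid = build_full_grid()
    nu = grid.values
    schedule, _ = _sample_schedule(cfg, rng)
    gt = concentration_profiles(cfg, analytes, rng=rng, schedule=schedule)
    n = len(schedule)

    pures = {a.name: pure_spectrum(a, grid) for a in analytes}
    solvent = _solvent_spectrum(grid)
    chem = solvent[None, :] + sum(
        gt.true_concentrations[name].to_numpy()[:, None] * p
        for name, p in pures.items())

    m = rng.normal(1.0, cfg.scatter_slope_sd, size=n)
    o = rng.normal(0.0, cfg.offset_sd, size=n)
    g = rng.normal(0.0, cfg.tilt_sd, size=n)
    nu_scaled = (nu - nu.mean()) / (nu.max() - nu.min())
    noise_sd = np.where(nu <= cfg.low_wn_threshold,
                        cfg.noise_sd_low_wn_region, cfg.noise_sd_base)
    eps = rng.normal(0.0, 1.0, size=(n, len(nu))) * noise_sd

    # the detector ceiling applies to the measured signal, after sample
    # scatter/baseline effects: the saturated plateau is identical
    # (uninformative) across samples
    absorbance = np.minimum(
        m[:, None] * chem + o[:, None]
        + g[:, None] * nu_scaled[None, :] + eps,
        cfg.saturation_ceiling)

    meta = pd.DataFrame({
        "sample_id": [f"S{i + 1:03d}" for i in range(n)],
        "batch_id": [f"B{b + 1}" for b, _ in schedule],
        "time_min": [t for _, t in schedule],
    })
    ds = SpectralDataset(
        absorbance=absorbance, grid=grid, sample_meta=meta,
        references=gt.true_concentrations.copy())

    gt.informative_variable_indices = {
        name: np.flatnonzero(p >= 0.1 * p.max()) for name, p in pures.items()}

    if cfg.n_outliers > 0:
        idx = rng.choice(n, size=cfg.n_outliers, replace=False)
        ds = plant_outliers(ds, gt, idx, cfg.outlier_mode, cfg=cfg, rng=rng)
    return ds, gt


def plant_outliers(ds: SpectralDataset, ground_truth: GroundTruth,
                   indices, mode: str = "concentration_shift",
                   cfg: SimulationConfig = SimulationConfig(),
                   rng: np.random.Generator | None = None) -> SpectralDataset:
    """Corrupt the given samples and record them in the ground truth.

    ``concentration_shift`` perturbs the *reference* values (an assay
    blunder: the spectrum no longer matches the recorded concentration)
    by +/- ``outlier_shift_mg_per_ml`` per analyte, far above the
    assay-jitter SD.  ``spectral_artifact`` adds a broad spurious band
    to the spectrum instead.
    """
    indices = np.asarray(indices, dtype=int)
    if len(indices) == 0:
        return ds
    if indices.min() < 0 or indices.max() >= ds.n_samples:
        raise IndexError("outlier index out of range")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    out = ds.subset_samples(np.arange(ds.n_samples))
    if mode == "concentration_shift":
        for k, i in enumerate(indices):
            sign = 1.0 if k % 2 == 0 else -1.0
            for col in out.references.columns:
                lo = out.references[col].min()
                shifted = out.references.iloc[i][col] + sign * cfg.outlier_shift_mg_per_ml
                # keep the blunder physically plausible (non-negative)
                out.references.iloc[i, out.references.columns.get_loc(col)] = (
                    max(shifted, 0.25 * lo))
    elif mode == "spectral_artifact":
        nu = out.grid.values
        band = 0.15 * np.exp(-0.5 * ((nu - 8800.0) / 400.0) ** 2)
        for i in indices:
            out.absorbance[i] += band
    else:
        raise ValueError(f"unknown outlier mode {mode!r}")
    ground_truth.outlier_indices = np.sort(
        np.union1d(ground_truth.outlier_indices, indices)).astype(int)
    return out
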