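"""End-to-end study workflow.

Order of stages (per-analyte models share the sample handling):

1. load or simulate the dataset (optionally average replicates)
2. exclude the saturated solvent band (5235-5078 cm^-1)
3. MCCV outlier screening on all samples; union of per-analyte flags
4. SPXY calibration/prediction split (shared, joint multi-analyte y)
5. pretreatment screen on the calibration set; winner applied to all
   samples using calibration-derived statistics
6. wavelength selection (any of sipls / cars / frog / vcpa-iriv) on the
   calibration set only
7. final PLS1 fit per method (LV by LOO CV on calibration) and external
   validation on the untouched prediction set

Prediction-set samples are never seen by any selection or LV-choice
step.  Every stochastic stage consumes a sub-seed derived from the
global seed and the stage name, so reruns are bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cars, frog, sipls, vcpa_iriv
from .outliers import combine_flags, flag_outliers, mccv_residuals
from .pls import evaluate, fit_pls, loocv_select_lv
from .preprocess import (PretreatmentConfig, apply_pretreatment, msc,
                         pretreatment_screen)
from .simulate import SATURATED_REGION, SimulationConfig, simulate_dataset
from .spectra import ExclusionInterval, exclude_region, read_dataset
from .spxy import spxy_split
from .subset import VariableSubset

__all__ = ["PipelineConfig", "StudyReport", "derive_seed", "run_pipeline",
           "write_report", "DEFAULT_PRETREATMENTS"]

log = logging.getLogger("nirsel.pipeline")

DEFAULT_PRETREATMENTS = (
    PretreatmentConfig(method="raw"),
    PretreatmentConfig(method="normalization"),
    PretreatmentConfig(method="snv"),
    PretreatmentConfig(method="msc"),
    PretreatmentConfig(method="sg_smoothing"),
)

DEFAULT_SELECTOR_PARAMS = {
    "sipls": {"n_intervals_range": list(range(10, 31)), "n_combine": 4},
    "cars": {"n_runs": 100, "calib_fraction": 0.8, "cv_folds": 5},
    "frog": {"n_iter": 10_000, "Q_init": 2, "variance_factor": 0.3,
             "accept_factor": 0.1, "top_n": 500, "step": 40},
    "vcpa_iriv": {"target_count": 100, "n_edf_loops": 5, "K_vcpa": 1000,
                  "K_iriv": 200, "best_frac": 0.15, "worst_frac": 0.05,
                  "alpha": 0.05},
}


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    return (seed * 2_654_435_761 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    seed: int
    simulation: SimulationConfig | None = None
    spectra_path: str | None = None
    reference_path: str | None = None
    analytes: list | None = None           # default: all reference columns
    exclusion: ExclusionInterval = SATURATED_REGION
    mccv_n_iter: int = 1000
    mccv_split_ratio: float = 0.75
    outlier_mode: str = "robust"
    split_ratio: float = 0.75
    split_per_analyte: bool = False
    pretreatments: tuple = DEFAULT_PRETREATMENTS
    selectors: tuple = ("sipls", "cars", "frog", "vcpa_iriv")
    selector_params: dict = field(default_factory=dict)
    max_lv: int = 10

    def __post_init__(self):
        have_files = self.spectra_path is not None
        if have_files == (self.simulation is not None):
            raise ValueError(
                "exactly one of simulation / input paths must be given")


@dataclass
class StudyReport:
    table1: pd.DataFrame
    table2: dict          # analyte -> pretreatment screen table
    table3: dict          # analyte -> SIPLS scan table (if run)
    table4: dict          # analyte -> method-comparison table
    table5: pd.DataFrame  # external validation of the winning models
    subsets: dict         # (analyte, method) -> VariableSubset
    models: dict          # (analyte, method) -> PLSModel
    outlier_flags: set
    split: dict           # analyte -> SplitResult (shared -> same object)
    pretreatment_winner: dict
    log_records: list = field(default_factory=list)


def _summary_rows(y, label, analyte):
    return {"analyte": analyte, "subset": label, "n": len(y),
            "min": float(np.min(y)), "max": float(np.max(y)),
            "mean": float(np.mean(y)), "std": float(np.std(y, ddof=1))}


def _run_selector(name, X, y, params, max_lv, seed):
    if name == "sipls":
        rng_range = params.get("n_intervals_range", list(range(10, 31)))
        subset, table = sipls.sipls_search(
            X, y, n_intervals_range=rng_range,
            n_combine=params.get("n_combine", 4), max_lv=max_lv)
        return subset, table
    if name == "cars":
        subset, trace = cars.cars_select(
            X, y, n_runs=params.get("n_runs", 100),
            calib_fraction=params.get("calib_fraction", 0.8),
            cv_folds=params.get("cv_folds", 5), max_lv=max_lv, seed=seed)
        return subset, trace.as_frame()
    if name == "frog":
        trace = frog.frog_probabilities(
            X, y, n_iter=params.get("n_iter", 10_000),
            Q_init=params.get("Q_init", 2),
            variance_factor=params.get("variance_factor", 0.3),
            accept_factor=params.get("accept_factor", 0.1),
            max_lv=max_lv, cv_folds=params.get("cv_folds", 5), seed=seed)
        subset, curve = frog.frog_refine(
            X, y, trace, top_n=params.get("top_n", 500),
            step=params.get("step", 40), max_lv=max_lv)
        return subset, curve
    if name == "vcpa_iriv":
        subset, artifacts = vcpa_iriv.vcpa_iriv_select(
            X, y, target_count=params.get("target_count", 100),
            n_edf_loops=params.get("n_edf_loops", 5),
            K_vcpa=params.get("K_vcpa", 1000),
            K_iriv=params.get("K_iriv", 200),
            best_frac=params.get("best_frac", 0.15),
            worst_frac=params.get("worst_frac", 0.05),
            alpha=params.get("alpha", 0.05),
            cv_folds=params.get("cv_folds", 5), max_lv=max_lv, seed=seed)
        return subset, artifacts["iriv_rounds"]
    raise ValueError(f"unknown selector {name!r} "
                     "(must be one of sipls, cars, frog, vcpa_iriv)")


def run_pipeline(config: PipelineConfig) -> StudyReport:
    t0 = time.perf_counter()
    records = []

    def tick(stage):
        records.append({"stage": stage, "t_s": time.perf_counter() - t0,
                        "sub_seed": derive_seed(config.seed, stage)})
        log.info("stage %s at %.1fs", stage, records[-1]["t_s"])

    # --- 1. data ---------------------------------------------------------
    if config.simulation is not None:
        sim = config.simulation
        if sim.seed != derive_seed(config.seed, "simulate"):
            sim = SimulationConfig(**{
                **sim.__dict__, "seed": derive_seed(config.seed, "simulate")})
        ds, _ = simulate_dataset(sim)
    else:
        ds = read_dataset(config.spectra_path, config.reference_path)
    if ds.references is None:
        raise ValueError("pipeline requires reference concentrations")
    analytes = list(config.analytes or ds.references.columns)
    tick("load")

    # --- 2. saturated-region exclusion -----------------------------------
    ds = exclude_region(ds, config.exclusion)
    tick("exclude")

    # --- 3. MCCV outlier removal ------------------------------------------
    flags = {}
    for a in analytes:
        rep = mccv_residuals(
            ds.absorbance, ds.references[a].to_numpy(),
            n_iter=config.mccv_n_iter, split_ratio=config.mccv_split_ratio,
            max_lv=config.max_lv, seed=derive_seed(config.seed, f"mccv:{a}"))
        flags[a] = flag_outliers(rep, mode=config.outlier_mode)
    removed = combine_flags(flags, how="intersection")
    keep = np.setdiff1d(np.arange(ds.n_samples), sorted(removed))
    ds = ds.subset_samples(keep)
    tick("outliers")

    # --- 4. SPXY split ----------------------------------------------------
    splits = {}
    if config.split_per_analyte:
        for a in analytes:
            splits[a] = spxy_split(ds.absorbance,
                                   ds.references[a].to_numpy(),
                                   ratio=config.split_ratio)
    else:
        shared = spxy_split(ds.absorbance,
                            ds.references[analytes].to_numpy(),
                            ratio=config.split_ratio)
        splits = {a: shared for a in analytes}
    tick("split")

    table1 = pd.DataFrame([
        _summary_rows(ds.references[a].to_numpy()[idx], label, a)
        for a in analytes
        for label, idx in (("Calibration set", splits[a].calibration_indices),
                           ("Prediction set", splits[a].prediction_indices))])

    # --- 5. pretreatment screen (calibration only) ------------------------
    table2, winners, treated = {}, {}, {}
    for a in analytes:
        cal = splits[a].calibration_indices
        y_cal = ds.references[a].to_numpy()[cal]
        table2[a] = pretreatment_screen(ds.absorbance[cal], y_cal,
                                        config.pretreatments,
                                        max_lv=config.max_lv)
        win = config.pretreatments[int(np.flatnonzero(
            table2[a]["winner"].to_numpy())[0])]
        winners[a] = win
        if win.method == "msc":
            # reference spectrum from calibration rows only (no leakage)
            ref = ds.absorbance[cal].mean(axis=0)
            treated[a] = msc(ds.absorbance, reference=ref)
        else:
            treated[a] = apply_pretreatment(ds.absorbance, win)
    tick("screen")

    # --- 6 + 7. selection, fit, validation --------------------------------
    table3, table4, subsets, models = {}, {}, {}, {}
    best_rows = []
    for a in analytes:
        sp = splits[a]
        X = treated[a]
        y = ds.references[a].to_numpy()
        X_cal, y_cal = X[sp.calibration_indices], y[sp.calibration_indices]
        X_prd, y_prd = X[sp.prediction_indices], y[sp.prediction_indices]
        rows = []
        cv_full = loocv_select_lv(X_cal, y_cal, max_lv=config.max_lv)
        rows.append({"method": "Global", "NV": X.shape[1],
                     "LVs": cv_full.chosen_lv, "Rcv": cv_full.rcv,
                     "RMSECV": cv_full.rmsecv, "RPDCV": cv_full.rpdcv})
        for name in config.selectors:
            params = {**DEFAULT_SELECTOR_PARAMS.get(name, {}),
                      **config.selector_params.get(name, {})}
            sub, aux = _run_selector(
                name, X_cal, y_cal, params, config.max_lv,
                seed=derive_seed(config.seed, f"select:{name}:{a}"))
            if name == "sipls":
                table3[a] = aux
            sub.wavenumbers = ds.grid.values[sub.indices]
            subsets[(a, name)] = sub
            cv_sub = loocv_select_lv(X_cal[:, sub.indices], y_cal,
                                     max_lv=min(config.max_lv, len(sub)))
            model = fit_pls(X_cal[:, sub.indices], y_cal,
                            n_lv=cv_sub.chosen_lv,
                            variable_indices=sub.indices)
            models[(a, name)] = model
            rows.append({"method": name, "NV": len(sub),
                         "LVs": cv_sub.chosen_lv, "Rcv": cv_sub.rcv,
                         "RMSECV": cv_sub.rmsecv, "RPDCV": cv_sub.rpdcv})
        table4[a] = pd.DataFrame(rows)
        sel_rows = table4[a][table4[a]["method"] != "Global"]
        best_method = sel_rows.loc[sel_rows["RMSECV"].idxmin(), "method"]
        sub = subsets[(a, best_method)]
        model = models[(a, best_method)]
        ev = evaluate(model, X_cal[:, sub.indices], y_cal,
                      X_prd[:, sub.indices], y_prd)
        best_rows.append({"analyte": a, "method": best_method,
                          "NV": len(sub), "LVs": model.n_lv, **ev.as_dict()})
    tick("select+fit+evaluate")

    return StudyReport(
        table1=table1, table2=table2, table3=table3, table4=table4,
        table5=pd.DataFrame(best_rows), subsets=subsets, models=models,
        outlier_flags=removed, split=splits,
        pretreatment_winner={a: winners[a].label for a in analytes},
        log_records=records)


def write_report(report: StudyReport, out_dir) -> None:
    """Serialize every table and artifact of a run as CSV/JSON text."""
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "stages").mkdir(parents=True, exist_ok=True)
    report.table1.to_csv(out / "tables" / "table1_split_summary.csv",
                         index=False)
    for a, t in report.table2.items():
        t.to_csv(out / "tables" / f"table2_pretreatments_{a}.csv",
                 index=False)
    for a, t in report.table3.items():
        t.to_csv(out / "tables" / f"table3_sipls_{a}.csv", index=False)
    for a, t in report.table4.items():
        t.to_csv(out / "tables" / f"table4_methods_{a}.csv", index=False)
    report.table5.to_csv(out / "tables" / "table5_external_validation.csv",
                         index=False)
    for (a, m), sub in report.subsets.items():
        with open(out / "stages" / f"subset_{a}_{m}.json", "w") as fh:
            json.dump(sub.to_dict(), fh, indent=1)
    for (a, m), model in report.models.items():
        with open(out / "stages" / f"model_{a}_{m}.json", "w") as fh:
            json.dump({
                "x_mean": model.x_mean.tolist(),
                "y_mean": model.y_mean,
                "b": model.b.tolist(),
                "n_lv": model.n_lv,
                "variable_indices":
                    None if model.variable_indices is None
                    else model.variable_indices.tolist(),
            }, fh)
    with open(out / "stages" / "run_log.json", "w") as fh:
        json.dump({"outliers_removed": sorted(report.outlier_flags),
                   "pretreatment_winner": report.pretreatment_winner,
                   "stages": report.log_records}, fh, indent=1)
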