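# Methods

This note documents the models, algorithmic conventions and numerical
choices behind `nirsel`, and what the synthetic-data experiments do and
do not demonstrate.

## Calibration model

All regression is single-response PLS1 computed by NIPALS on
mean-centered data (no autoscaling: absorbance variables share units,
and the reproduced printed-table metrics are consistent with centering
only). For one response the NIPALS component is non-iterative — the
weight vector is the normalized covariance X′y of the deflated
predictor block with the centered response — so a full decomposition to
`max_lv` components costs O(max_lv · n · p). The regression vector on
the original variable scale is accumulated per component through
r_a = w_a − Σ_{j<a} (p_j·w_a) r_j, which gives predictions for every
component count from a single decomposition; leave-one-out
cross-validation (LOO CV) over a component grid therefore needs only n
decompositions.

Component count: `max_lv` defaults to 10 everywhere (the conventional
cap for process-NIR calibrations of this kind); the chosen count is the
first minimum of RMSECV over 1..max_lv (parsimony on ties). Requests
beyond min(n−1, p) or the effective rank are truncated with a warning.

### Metrics

* RMSE uses denominator n.
* R is the Pearson correlation between reference and predicted values;
  for LOO CV it is computed on the pooled hold-out predictions (the
  only well-defined choice for leave-one-out).
* RSE (%) = 100·√(Σ(ŷ−y)² / Σy²) = 100·RMSE/√(ȳ² + σ²ₚₒₚ).
* RPD = σₚₒₚ/RMSE with the population (denominator-n) SD.

The population-SD convention and the RSE identity jointly reproduce
seven of the eight RSE/RPD cells of the published external-validation
table to the printed two decimals from the reference-set moments alone
(the eighth differs by one final digit, consistent with the authors
using an unrounded RMSEP); this is what `scripts/acceptance.py`
recomputes.

### Inner scorer for Monte Carlo selectors

CARS, random frog and VCPA evaluate thousands of candidate subsets; a
full LOO CV inside those loops is wasteful. They use a seeded k-fold
scorer (default 5 folds) in which the y-sorted samples are dealt
round-robin, so every fold spans the response range; the score is the
best RMSE over component counts. Every method's *final* subset is
re-scored by LOO CV so that the reported RMSECVs are comparable across
methods. Which CV the original algorithms used internally is not
specified in the sources they derive from; this choice is pragmatic and
config-exposed.

## Synthetic campaign generator

The generator emulates an in-line NIR transmission campaign over an
alcohol-precipitation process, with known ground truth:

* **Grid** — uniform descending axis, 12,000 → 4,000 cm⁻¹, 2,072
  points (spacing ≈ 3.863 cm⁻¹, i.e. half the 8 cm⁻¹ instrument
  resolution). Removing the closed saturated window [5,078, 5,235]
  cm⁻¹ leaves exactly 2,032 variables, the canonical full-spectrum
  size for this application.
* **Concentrations** — per batch, both analytes follow
  c(t) = c₀·V₀/(V₀ + r·(t−t₀)) with a batch-specific dilution rate
  r ~ U(0.013, 0.023) min⁻¹ and starting concentrations drawn near the
  top of each analyte's admissible range (glycoside 2.74–7.82 mg/mL,
  flavonoid 1.76–4.72 mg/mL). The *shared* denominator is what makes
  the two analytes' profiles strongly correlated (r > 0.9 across a
  campaign), as in real ethanol-addition dynamics. Sampling starts at
  t = 90 min at 10-min intervals; batch durations vary in
  [150, 170] min; extra randomly-timed samples top the campaign up to
  101. Reference values carry multiplicative lognormal jitter with
  σ = 0.005 (0.5 % RSD, typical repeatability of a validated HPLC
  assay for these markers).
* **Spectra** — Beer–Lambert mixture of Gaussian pure-component bands
  (glycoside near 10,400/7,600/6,000/4,300 cm⁻¹; flavonoid near
  10,200/6,500/4,400 cm⁻¹, its aromatic C–H overtone shifted to
  ~6,500 cm⁻¹) over a fixed aqueous-ethanol background whose strong
  O–H combination band at ~5,160 cm⁻¹ saturates. Per-sample effects:
  multiplicative scatter m ~ N(1, 0.01) on the chemical part, additive
  offset N(0, 0.005), linear baseline tilt N(0, 0.002) across the
  axis, and white noise with SD 0.001 AU, elevated to 0.005 AU below
  4,413 cm⁻¹ (detector roll-off). The detector ceiling (2.5 AU) clips
  the *measured* signal, after scatter — so the saturated plateau is
  identical across samples, i.e. genuinely uninformative.
* **Outliers** — `concentration_shift` (default) perturbs a sample's
  *reference* values by ±1 mg/mL, an assay blunder that leaves the
  spectrum untouched; `spectral_artifact` adds a broad spurious band
  instead. Planted indices are recorded in the ground truth, as are
  the informative variable sets (grid points where a pure spectrum
  exceeds 10 % of its maximum).

One seeded generator drives every draw, so a fixed seed reproduces a
campaign bit for bit.

**What passing tests on this generator show** — that each algorithm
does what it claims under a linear mixture model with realistic
collinearity, scatter, heteroscedastic noise and outlier structure:
selectors recover planted informative bands, MCCV separates planted
reference blunders from clean samples, SPXY covers the reference range.
**What they do not show** — robustness to nonlinear detector response,
temperature-dependent band shifts, batch-wise chemical interferents or
drift, none of which the generator models. Real plant data are harder
than this simulation in exactly those directions.

## Stage conventions and design decisions

* **Stage order** — exclusion of the saturated band precedes
  everything; MCCV outlier screening runs on all samples *before* the
  pretreatment screen and the split (the screen is then computed on
  calibration rows only); SPXY runs on raw post-exclusion spectra.
* **MCCV** (1,000 iterations, 75:25): the PLS component count is
  chosen once by LOO CV on the full data and held fixed across
  iterations. The residual is |observed − predicted| per hold-out
  occurrence; per-sample SD uses denominator k−1 (0 for a single
  occurrence). Robust flagging uses the fence
  median + 5·MAD per statistic, with MAD the normal-consistent
  estimator (1.4826 × raw MAD), the standard convention for
  median ± k·MAD outlier fences. Per-analyte flag sets are combined by
  *intersection*: a sample is removed only when every analyte's screen
  flags it — a sample flagged by a single assay alone is retained.
  Absolute cutoffs and an AND/OR connective are available for
  screening against user-chosen thresholds.
* **SPXY** — joint distance d = dx/max(dx) + dy/max(dy), Euclidean in
  both blocks (multi-analyte y uses the Euclidean distance over the
  analyte vector; the pipeline default is one split shared by all
  analytes); |calibration| = ⌊ratio·n⌋, so 99 samples at 3:1 give
  74/25; ties break toward the smallest sample index, making the split
  fully deterministic.
* **SIPLS** — p variables into n equal intervals (the first p mod n
  intervals one variable longer); all C(n, 4) combinations scored by
  LOO RMSECV; global winner over n = 10..30 with ties broken toward
  fewer variables, then lexicographic combination order.
* **CARS** — retention ratios follow the exponentially decreasing
  function pinned to keep all p variables at run 1 and 2 at run N.
  The adaptive reweighted sampling draws p times (the original
  variable count) with replacement, probability ∝ |b|, from the
  forced-kept set — the canonical draw count; drawing only the
  EDF-scheduled count compounds the de-duplication loss and collapses
  the set within a few runs. No resampling is applied on the first
  run, where the schedule retains everything. Monte Carlo fit fraction
  0.8.
* **Random frog** — Q_init = 2, dimension proposals from
  N(Q, 0.3·Q), candidate growth recruits from a random pool of
  3×(Q*−Q) outside variables ranked by |b|, worse candidates accepted
  with probability 0.1·RMSECV(V)/RMSECV(V*). Counts accumulate for the
  subset held at the *start* of each iteration. Refinement ranks by
  selection probability (ties toward smaller index) and LOO-scores
  nested prefixes of sizes top_n, top_n−step, … (defaults 500 by 40,
  i.e. 13 subsets down to size 20).
* **VCPA–IRIV** — per EDF loop, K binary-matrix-sampled sub-models
  (inclusion ratio 0.5, rows with <2 ones redrawn); variable score =
  frequency in the best 15 % of sub-models minus frequency in the
  worst 5 %; the space shrinks along the EDF to 100 variables. IRIV
  refits each sub-model with the variable flipped out (paired design),
  classifies by the sign of the mean RMSECV difference and a two-sided
  Mann–Whitney test at α = 0.05, deletes uninformative + interfering
  variables and repeats to convergence. Backward elimination accepts
  the best single removal whose LOO RMSECV does not worsen the current
  value beyond 1e-10 relative tolerance — equality counts as
  removable, so perfectly collinear duplicates are pruned — and stops
  when every removal strictly worsens it.
* **Pipeline determinism** — every stochastic stage consumes a
  sub-seed derived from the global seed and the stage name; reruns are
  byte-identical. Selection and component choice see calibration rows
  only; the prediction set is touched exactly once, by the final
  external validation.

## Problem sizes used in tests and reproduction

The test suite and the acceptance script favour many seeded replicates
over single large runs: selector-recovery studies use 20 seeds at
n = 50, p = 200 (or p = 60 for the full VCPA–IRIV chain with
K = 80/60 sub-models); the end-to-end pipeline test runs all four
selectors on a full 101 × 2,032 campaign with reduced search breadth
(one SIPLS interval count with pairwise combinations, 50 CARS runs,
a 1,000-iteration frog chain, a 2-loop/K = 100 VCPA); MCCV screening
always runs at its full 1,000 iterations. Paper-scale selector
settings (SIPLS 10..30 × C(n,4), 10,000-iteration frog chains,
K = 1,000 VCPA) are the module defaults and run unchanged — they are
simply more compute than a test suite warrants.

## Known limitations

* The MCCV robust fence occasionally (≈1 campaign in 5) also removes
  one clean sample whose scatter or tilt draw is a ≥2.5σ extreme —
  arguably correct behaviour for a screen, but it means the retained
  count is 98 rather than 99 in those campaigns.
* SNV and MSC divide each row by a concentration-dependent scale, so
  on noiseless linear data they leave a small (~1e-4) nonlinearity
  floor; the linear pretreatments (normalization, SG smoothing) do
  not.
* Random frog is a faithful member of the trans-dimensional
  subset-sampling family, not a move-for-move reimplementation of any
  particular published chain; its hyperparameters are conventional
  defaults and config-exposed.
* PLS1 only (one analyte per model); multi-response PLS2, kernel PLS
  and uncertainty quantification are out of scope.
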