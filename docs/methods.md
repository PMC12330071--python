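# Methods

This note documents the statistical model implemented in `scplm`, the
numerical choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## The model

Peptide intensities are analyzed on the log2 scale at the peptide level
(PSM/precursor tables are aggregated first). For peptide *j* observed in
the cell set `O_j`:

    Y[O_j, j] = X[O_j, S_j] β[S_j, j] + ε[O_j, j],   ε ~ N(0, σ_j²)

One design matrix `X` (cells × parameters) is shared by all peptides. It
always carries an intercept in column 0; categorical descriptors are
encoded with sum-to-zero contrasts (a levels → a−1 columns, lexicographic
level order, last level −1 in every column of its block) so that the
intercept is the peptide's grand baseline and each level's effect is a
deviation from it; numeric descriptors are centered at their global cell
mean so the intercept keeps that meaning across peptides. The per-cell
normalization factor (median of observed log2 intensities) is just
another centered numeric covariate, computed on demand when the model
formula names `median_intensity`.

### Per-peptide adaptation (`S_j`)

Missing values are handled by adapting the model, not the data:

1. keep every column whose variance over `O_j` exceeds 1e−12 (absolute),
   plus the intercept;
2. drop columns that are linearly dependent on earlier retained columns
   (greedy order-preserving rank filter with a 1e−10 relative residual
   tolerance).

Step 2 goes beyond the constant-column rule for a specific reason: when a
whole categorical level is unobserved (a peptide absent from an entire
MS run), sum coding leaves no constant column but makes the subsetted
design rank-deficient. A penalized exact fit then minimizes the
coefficient norm by smearing the large intercept (~7 log2 units) across
the aliased parameters, which corrupts both the effect matrices and the
batch-corrected reconstruction. Dropping the dependent column instead
leaves the unidentifiable part of that family in the intercept, where it
is interpretable as "baseline over the observed runs". Earlier columns
win, so the intercept and the first formula variables take precedence.

### Estimability filter and fit

`n/p = |O_j| / |S_j|` must exceed 1 for the residual degrees of freedom
`ν = |O_j| − |S_j|` to be positive; peptides with `n/p ≤ 1` are always
skipped, and a stricter threshold (e.g. 3) can be requested. Coefficients
are the ridge solution `(XᵀX + λI)⁻¹Xᵀy` with `λ = 10⁻³` by default —
a numerical stabilizer, not a shrinkage device. Consequently:

- the residual degrees of freedom are counted as the OLS `ν = n − p`,
  without a ridge effective-df correction (at λ = 10⁻³ the difference is
  far below the noise level of σ̂²);
- numeric covariates are *not* re-centered per peptide after row
  subsetting, keeping one design shared across peptides;
- at λ = 0 on full-rank systems the fit, SSE and σ̂² coincide with
  ordinary least squares (this is tested).

## Analysis of variance

Per peptide, `SSR⁽ᶠ⁾ = ‖X[O_j, K_f∩S_j] β̂‖²` for each model variable
and `SSE = ‖ε̂‖²`; percentages are normalized by `SSE + Σ_f SSR⁽ᶠ⁾` so
they sum to 100 per peptide. The intercept is a baseline, not a variance
source, and is excluded from the components. Variables entirely dropped
for a peptide are reported with 0 % rather than omitted, keeping tables
rectangular. Global and protein-level summaries are unweighted means of
the peptide percentages (so they also sum to 100).

Because SSR blocks are not mutually orthogonal in unbalanced/subsetted
designs, the decomposition is descriptive, not an orthogonal partition;
this matches its intended use as an exploration layer.

## Differential abundance

The coefficient covariance uses the ridge sandwich form
`(XᵀX+λI)⁻¹ XᵀX (XᵀX+λI)⁻¹ σ̂²`. A group contrast is the difference of
the two groups' sum-contrast encoding rows, so `Lβ̂` is the model-implied
mean difference (a log2 fold change). `T = Lβ̂/√(LVLᵀ)` is referred to
`t_ν`, two-sided. Contrasts loading on a dropped parameter are reported
as non-estimable (NaN estimate and p) rather than silently removed —
the missing pattern itself is informative.

Multiple testing: plain Benjamini–Hochberg, or a binned
independent-hypothesis-weighting scheme — estimable tests are stratified
into 5 quantile bins of baseline (intercept) intensity; with 2 folds,
each fold's per-bin weights are learned on the complementary fold by a
seeded random search (200 Dirichlet candidates, mean-weight-1 budget)
maximizing weighted-BH discoveries at α = 0.05; a single weighted BH
(p/w) is then applied. With fewer than 10 × n_bins tests the scheme
falls back to plain BH. The rationale for baseline weighting: peptides
with high baseline intensity are measured more reliably and deserve less
multiple-testing penalty.

Protein-level combination implements seven classical methods (Fisher,
Simes, Berger, Pearson, min-Holm, Stouffer, Wilkinson r = 1). Every
method reduces to the identity for single-peptide proteins (tested). The
representative peptide is the one determining the combined statistic
(max-p for Berger, min-p otherwise; ties broken by larger |logFC|, then
peptide id), and the protein log fold change is that peptide's estimate.

## APCA+ component analysis

For variable *f*, the augmented effect matrix `A⁽ᶠ⁾ = M̂⁽ᶠ⁾ + ε̂` is
oriented cells × features (cells are the score space), centered
feature-wise on observed entries, and decomposed by NIPALS. No
unit-variance scaling is applied. Special names: `residual` (residuals
only) and `unmodelled` (PCA of the processed matrix itself, the
pre-modeling view).

NIPALS numerical choices:

- initialization from the column with the largest observed variance
  (deterministic);
- a component is accepted when the loading vector changes by < 1e−9 or
  after 500 iterations (slow power-iteration convergence occurs when
  eigenvalues are nearly equal and is resolved by the refinement below);
- deflation subtracts the rank-1 reconstruction on observed entries;
- **joint ALS refinement**: greedy one-at-a-time extraction is exact on
  complete data but only approximate under missingness (the mask breaks
  component orthogonality; residual reconstruction error plateaus at a
  few percent on low-rank matrices). After extraction, alternating
  row-/column-wise least squares over the whole k-dimensional subspace
  is run to convergence and the factors re-orthogonalized through a
  k×k SVD in factored form. On complete data this is a no-op; with
  missing data it brings the observed-entry reconstruction of a rank-3
  matrix with 20 % MCAR below 0.01 % error;
- deterministic sign convention: each loading vector's largest-magnitude
  element is made positive;
- percent variance per component = eigenvalue / total observed variance
  of the centered matrix.

Protein loadings are medians of the constituent peptide loadings; this
breaks orthogonality and variance-maximality and is offered as a
pragmatic exploration device only.

## Batch-corrected reconstruction

`intercept effect + Σ_{f∈keep} effect matrix + residuals`, with the
missing pattern preserved. Keeping all variables reproduces the data
exactly on observed entries; keeping only the biological variables
removes run/label/normalization structure. On simulated data with strong
run effects, refitting the model on the cell-type-only reconstruction
attributes < 1 % of the variance to the run (tested).

## Benchmark harness

NIPALS PCA (20 PCs by default) → k-means (k = number of expected cell
types; seeded, 10 restarts, best inertia) → ARI, NMI (arithmetic-mean
normalization, recorded here because the normalization is a genuine
choice), purity; silhouette (ASW, Euclidean) is computed on the PC
scores against the known labels directly. Technical scores are reported
as 1 − metric so higher is always better. ARI/NMI/ASW are delegated to
scikit-learn; purity is implemented here; all four are cross-checked
against brute-force oracle implementations in the test suite.

## Synthetic data generator

The generator emulates, on the log2 scale: per-peptide baselines
N(7, 1) (centered in the 6–8 median-log window typical of these data);
per-peptide run effects (sd 1.0), label effects (sd 0.2) and cell-type
effects (sd 0.5), each drawn Gaussian and re-centered to sum to zero so
the truth aligns exactly with the sum-contrast encoding; per-cell size
factors (sd 0.2); Gaussian residual noise (sd 0.5); MCAR missingness
(rate 0.3) plus structural run dropout (a peptide absent from a whole
run with probability 0.05). Defaults describe a modest multiplexed
experiment — 200 cells in 4 runs, 3 label channels, 2 cell types, 300
peptides over 100 proteins — with technical variance dominating
biological variance, the ordering reported for real SCP data. Cells are
assigned to runs in contiguous blocks and labels cycle within a run.

What it does **not** emulate: intensity-dependent (MNAR) missingness —
deliberately, since the modeling approach assumes missingness is
unrelated to intensity; correlated peptides within a protein beyond the
shared truth structure; heavy-tailed or heteroscedastic residuals;
carrier-channel or co-isolation artifacts; confounding of cell type with
run (types are randomized across runs). Passing tests therefore show
calibration and recovery under MCAR+dropout Gaussian conditions, not
robustness to MNAR or to type–batch confounding.

A note on recovery metrics: the size factor is shared by all peptides in
a cell and is not part of the `run + label + celltype` truth encoding,
so it acts as a per-cell noise floor. Halving the residual sd therefore
reduces the cell-type coefficient RMSE by slightly less than half
(expected ratio ≈ 0.6 at the default sds). Peptides affected by run
dropout keep calibrated cell-type inference, but their intercept and
run-family coefficients are identified only up to the observed runs
(see the rank-filter discussion above).

## Processing defaults

- Log base 2 (configurable); the median-log QC window (6, 8) and the
  per-cell median normalization factor are interpreted on this scale.
- The within-protein CV for cell QC: each peptide's intensities are
  divided by that peptide's mean across cells; for each protein with at
  least 3 (configurable) peptides observed in a cell, CV = sample sd /
  mean of those relative intensities; the cell's value is the median
  protein CV. Computed on raw intensities only.
- Peptides mapping to several proteins raise an error by default;
  `drop` and `keep-first-alphabetical` policies are available.
- Pipeline order is fixed: feature QC → cell QC → aggregation → log.
  Filtering is idempotent; aggregation marks a peptide observed in a
  cell iff at least one child is observed there (median of observed
  children).
- Zero raw intensities are converted to missing at ingestion (a reported
  zero means "not quantified"); the log transform rejects non-positive
  observed values. Log-scale zeros (intensity 1) are legitimate.

## Known limitations

- No linear mixed models / random effects, and no interaction terms; a
  fixed-effects linear model is fit per peptide.
- No empirical-Bayes variance moderation; σ̂² is per-peptide.
- The IHW variant is a binned cross-weighted BH, not the original convex
  optimization; plain BH is always available for exact reproducibility.
- The ANOVA decomposition is non-orthogonal in unbalanced designs.
- Protein-level loadings and log fold changes are representative-peptide
  summaries, not model-based protein estimates.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: 50 random systems for the OLS limit; 300 peptides × 100 cells for
variance conservation; 2000 null peptides for p-value uniformity; 50
replicates of 300 × 200 (two noise levels) for coverage and RMSE
scaling; 30×8 and 40×25 matrices for NIPALS fidelity; one 300 × 200 data
set for the batch-correction benchmark; 20 random labelings for the
metric oracles. These sizes keep a full run in the low minutes on one
CPU while leaving the stochastic checks well-powered.
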