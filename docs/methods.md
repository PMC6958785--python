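# Methods

## The problem

Bulk DNA methylation of a solid-tumour biopsy is a convex mixture of the
methylomes of its constituent cell populations.  Writing the observed
beta-value matrix as D (M CpG probes × N samples), the model is

    D = T A,      0 ≤ T ≤ 1,   0 ≤ A ≤ 1,   Σ_k A_kn = 1,

with T (M × K) the unknown cell-type-specific methylation profiles and
A (K × N) the unknown per-sample mixing proportions.  "Reference-free"
means both factors are estimated from D alone.  The practical obstacles
this package addresses are (i) measured confounders — sex, age, batch —
that add variance unrelated to cell composition, (ii) choosing the number
of cell types K, and (iii) scoring estimates when components are
recovered only up to relabeling.

## Factorization

The estimator minimizes

    ‖D − TA‖²_F + λ Σ_ij ω(T_ij),   ω(x) = x(1 − x),

by alternating exact subproblem solves:

* **A-step.**  Each sample's column solves a simplex-constrained least
  squares problem (non-negativity plus a sum-to-one equality; a
  sum-at-most-one variant handles the inequality convention via an
  explicit slack variable).  An active-set method solves the KKT system
  of each free-variable pattern exactly; iterations run synchronously
  over all columns, grouped by pattern, so each distinct system is
  factorized once per round.  Termination: primal and dual KKT residuals
  below 1e−8.
* **T-step.**  Each probe row solves a box-constrained quadratic.  All
  rows share the K × K Gram matrix A Aᵀ, so cyclic coordinate descent
  over the K type coordinates is vectorized across the M rows, with
  exact one-dimensional minimizers (interior clip in the convex case).
  When λ exceeds the corresponding diagonal curvature the 1-D pieces turn
  concave and the update takes the better endpoint; the result is then a
  stationary point rather than a certified global row minimum, matching
  the behaviour of the ω-penalty, which deliberately pushes entries to
  the extremes.  Sweeps stop when no coordinate moves more than 1e−9
  (cap 100 sweeps per call).

Both steps never increase the objective, so the objective trajectory is
non-increasing (asserted in tests at λ = 0 to 1e−9 per iteration).

**Initialization.**  Three families, reflecting common practice:
random proportions (columns of A from a flat Dirichlet), hierarchical
clustering of the sample columns (ward/euclidean by default,
complete/manhattan available) with per-cluster mean profiles as initial
T columns, and truncated SVD with each row of the leading left singular
block binarized at its row median (the initial T is binary, hence
penalty-free).  A user-supplied T is also accepted.  Multi-start
(default NINIT = 10, seeds = master seed + restart index) keeps the
lowest-objective run; only the Dirichlet initialization is stochastic,
so deterministic initializations run once.

**Defaults.**  λ = 0 with the conventional grid
{0, 1e−5, 1e−4, 1e−3, 1e−2, 0.1} exposed; max_iter = 300;
relative objective tolerance 1e−6; constraint mode sum-to-one.

## Pre-processing

* **Confounder-probe removal** (the critical stage): for each measured
  covariate, a per-probe single-covariate association test — the slope
  t-test (equivalently the Pearson-correlation t-test, N − 2 df) for
  numeric covariates, a one-way ANOVA F-test for categorical ones such
  as plate.  A slope test is undefined for an unordered factor, and the
  F-test is its natural single-covariate analogue; this is the one point
  where the implementation refines the stated regression recipe.
  P-values are Benjamini–Hochberg adjusted across all probes within each
  covariate, probes with adjusted p ≤ 0.15 are flagged, and the union of
  flags over covariates is removed.  Constant covariates are skipped
  with a warning; zero-variance probes get p = 1.
* **Feature selection** (optional): variance filter (keep var > 0.02,
  strict, across samples, ddof = 1); PCA filter (probe-centered
  covariance PCA, keep probes with Pearson p < 0.1 against **any** of
  the first 4 component score vectors — the ANY reading is the
  configurable default, `mode="all"` is available); informative loci
  from grouped reference profiles (one-vs-rest Welch tests, top 500 at
  p < 1e−4 by minimum p over groups, plus the top 100 per requested
  pairwise contrast, unioned; singleton groups fall back to
  absolute-mean-difference ranking with a warning).

Filters only select rows — retained values are never altered — and the
variance filter is exactly idempotent.

## Choosing K

* **Scree + Cattell's rule.**  Eigenvalues of the sample covariance of
  probe-centered D, in descending order.  A noiseless K-type mixture
  with sum-to-one proportions lies in an affine subspace of dimension
  K − 1, so K − 1 eigenvalues rise above the noise floor and the
  estimate is K̂ = retained PCs + 1.  The visual elbow is automated:
  over components 1..L (L = min(30, available)), draw the chord from
  (1, λ₁) to (L, λ_L) and take the component with maximum vertical gap
  below the chord; retained PCs = elbow − 1.  If no gap exceeds
  1e−8 × λ₁ (e.g. strictly linear decay) the result is a "no elbow"
  sentinel (`k_hat = None`).  The tolerance is relative so the rule is
  scale-invariant.  Active confounders add apparent mixture dimensions
  (a binary sex shift is exactly rank one), inflating K̂ by one; probe
  removal restores the correct elbow — this interaction is the central
  behaviour the acceptance checks exercise.
* **Subset stability.**  For each candidate K, refit on ≥ 3 random 80%
  sample subsets; after matched-component alignment (by proportion rows
  on shared samples) the stability scores are the mean pairwise Pearson
  correlations of matched T columns and matched A rows.  Chosen K =
  largest candidate with both scores above 0.9 (the threshold is a
  package default; no canonical value exists).
* **Leave-columns-out cross-validation.**  Fit T on training columns,
  refit A on held-out columns with T fixed, score mean held-out squared
  error per entry over a (K, λ) grid (default 10 folds).  Because extra
  T columns act as extra regressors for the held-out A-step, the CVE
  decreases (weakly) beyond the true K rather than turning upward; the
  informative signal is the decay profile — a sharp drop up to the true
  K, then a plateau — not the argmin.  The function therefore returns
  the full table and the tests assert the decay-elbow property.

## Evaluation

Estimated components are paired with true components by the injective
assignment minimizing the mean absolute error of paired proportion rows
(exhaustive search with lexicographic tie-breaking for min(K) ≤ 8,
optimal linear assignment above; the cost decomposes per pair so both
are exact).  Matched MAE and RMSE average over paired entries only;
when the fitted K exceeds the true K the surplus components are left
unpaired, and in the opposite direction a best subset of true components
is paired (the denominator counts paired types in both cases —
the convention for the under-specified direction is this package's
choice).  Profile quality is scored as the Pearson correlation of every
(estimated, reference) T-column pair on the intersected probe set;
constant columns give a missing value.

## Synthetic data

No reference methylomes are downloaded; the generator reproduces the
statistical structure the pipeline is sensitive to.

* **Profiles.**  Beta values are drawn from the canonical bimodal array
  distribution (equal mixture of Beta(2, 20) and Beta(20, 2), modes near
  0.05 and 0.95).  A fraction `frac_informative` (default 0.2) of probes
  is cell-type informative: their per-type values interpolate between a
  shared baseline draw and independent per-type draws with weight
  `divergence` (default 0.8).  Defaults were chosen to mimic real
  purified profiles, where roughly 10–25% of CpGs are differentially
  methylated between cell types with effect sizes that are large on the
  beta scale; they also reproduce the qualitative scree shapes of real
  mixtures (a convex decay of K − 1 signal eigenvalues over a flat
  noise bulk).
* **Proportions.**  Columns of A are Dirichlet with concentration
  α₀ × base_props, base_props = (0.10, 0.60, 0.05, 0.15, 0.10) for
  (fibroblast, cancerous epithelial, T lymphocyte, control epithelial,
  cancerous mesenchymal) and (0.20, 0.70, 0.10) for the 3-type variant.
  The concentrations sum to α₀, so α₀ ≈ 1 gives highly diverse mixtures
  and α₀ → ∞ concentrates all samples at base_props.
* **Confounders.**  1397 sex probes receive an additive shift (same
  coefficient in every cell-type column) for the sex = 1 group —
  magnitude effect_scale × U(0.5, 1.5), random sign, emulating probes
  pre-selected for a significant association; 113 age probes are
  overwritten by a linear-in-age prediction assigned to the designated
  epithelial type and propagated to other types by per-probe ratio
  coefficients (type value over epithelial value in the base profiles,
  so zero effect scale is exactly the identity); 22 plates carry
  multiplicative coefficients 1 + effect_scale × U(−0.1, 0.1) with the
  reference plate fixed at 1.  Sex/age probe sets are disjoint so each
  probe carries one confounder.  Default effect_scale = 0.2.
* **Assembly.**  Stage order sex → age → mix → plate → noise (plate and
  noise order switchable).  Confounder shifts clamp to [0, 1]; the final
  Gaussian noise stage (sd ε, default 0.2) instead uses a
  skip-at-boundary rule — a draw that would leave [0, 1] is discarded
  and the entry kept unchanged, which slightly deflates effective noise
  at the bimodal extremes but never clips.  All stage seeds derive from
  one integer seed.

**What the generator does not model:** Infinium type-I/II probe
chemistry, genome-wide correlation structure between neighbouring CpGs,
cell–cell interaction effects on methylation, population substructure in
the covariates, and real effect-size distributions estimated from
clinical cohorts.  Passing tests therefore demonstrate correctness of
the pipeline's mechanics and the direction and rough magnitude of the
pre-processing effects, not clinical-grade error levels on real tumours.

## Numerical and design notes

* Active-set rounds are capped at 4K + 8 per A-step; on the (never
  observed) cap the current iterate is projected to the simplex and a
  warning logged.
* Cluster initialization orders components by cluster label; degenerate
  cuts pad with duplicated columns.
* Ties in the SVD binarization (entry equal to its row median) go to 1.
* Ties between assignments in component matching break lexicographically.
* Under-sized subsets (stability) and infeasible benchmark combinations
  are skipped/flagged with warnings, not fatal.
* Benchmark problem sizes used in tests and the acceptance script —
  10,000 probes × 100 samples for the scree and deconvolution studies,
  10,000 samples for the Dirichlet calibration, 5–10 seeded replicates —
  are the package's standard desk-scale settings; all are overridable.

## Known limitations

* The factorization converges to local optima; multi-start mitigates but
  does not remove initialization sensitivity (visible at α₀ ≫ 1, where
  mixtures are near-identical and recovery degrades for all methods).
* The confounder filter tests one covariate at a time; correlated
  covariates or confounders interacting with cell type violate its
  assumptions.
* Leave-columns-out CVE cannot penalize overfitting K by design (see
  above); prefer the scree rule after probe removal.
* With the synthetic profile generator, the error penalty for fitting
  K = K_true + 1 is reproducibly present but smaller (≈ 1.6–1.7× over
  seeds) than what mixtures of real purified profiles exhibit; the
  magnitude depends on the between-type correlation structure of the
  profile set.
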