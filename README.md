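# methdeconv

Reference-free cell-type deconvolution of bulk DNA methylation, with the
pre-processing that makes it work.

Bulk methylation of a heterogeneous tissue (a tumour biopsy, say) is a
convex mixture of the methylomes of its constituent cell types.  Given a
beta-value matrix **D** (M CpG probes × N samples), the package estimates
both the cell-type-specific profiles **T** (M × K) and the per-sample
mixing proportions **A** (K × N) under the model

```
D ≈ T A,    0 ≤ T ≤ 1,  0 ≤ A ≤ 1,  Σₖ A_kn = 1
```

by constrained alternating least squares, optionally regularized by
λ · Σ T(1−T), which pushes inferred profiles toward the biologically
plausible methylation extremes 0 and 1.

The harder part of the problem is everything around the factorization,
and that is what this package packages:

* **simulation** of ground-truthed cohorts: Dirichlet mixing proportions
  (concentration α₀ × base proportions), per-individual profile
  perturbations by sex and age, multiplicative plate (batch) effects,
  and boundary-respecting Gaussian noise — so every pipeline stage can
  be validated against known truth;
* **confounder handling**: per-probe association tests against measured
  covariates (sex, age, plate, …) with Benjamini–Hochberg FDR control,
  removing probes whose variation is not about cell composition;
* **feature selection**: variance, principal-component correlation, and
  reference-based informative-loci filters;
* **choice of K**: the scree plot with an automated Cattell elbow rule
  (K̂ = retained PCs + 1), subset-stability analysis, and
  leave-columns-out cross-validation;
* **evaluation**: matched-component MAE/RMSE (components are recovered
  only up to relabeling, so estimated types are optimally assigned to
  true types first) and profile correlation heat-map tables.

It is aimed at methods developers and analysts benchmarking
reference-free deconvolution pipelines on methylation arrays
(Illumina 27K/450K-style beta values).

## Worked example

```python
import numpy as np
from methdeconv import (
    DeconvolutionConfig, SimulationConfig, cattell_k, fit, mae, rmse,
    make_cohort, make_confounder_effects, make_reference_profiles,
    match_components, remove_confounded_probes, scree_eigenvalues,
    simulate_dataset,
)

# 1. a ground-truthed cohort: 5 cell types, 10,000 probes, 100 samples,
#    diverse mixtures (alpha0=1), noise sd 0.2, sex/age/plate effects on
profiles = make_reference_profiles(n_probes=10_000, n_types=5, seed=1)
cohort = make_cohort(n_samples=100, seed=2)
effects = make_confounder_effects(profiles, seed=3)
config = SimulationConfig(n_samples=100, n_types=5, alpha0=1.0, epsilon=0.2, seed=4)
D, truth = simulate_dataset(config, profiles, cohort, effects)

# 2. remove confounder-associated probes (BH FDR 0.15)
filt = remove_confounded_probes(D, cohort, ["sex", "age", "plate"])
D_clean = filt.apply(D)
print(f"removed {filt.n_removed} confounder-associated probes, kept {filt.n_kept}")

# 3. how many cell types?  scree elbow before vs after filtering
print("K_hat raw     :", cattell_k(scree_eigenvalues(D)).k_hat)
print("K_hat filtered:", cattell_k(scree_eigenvalues(D_clean)).k_hat)

# 4. deconvolve at K=5 (10 random restarts) and score against the truth
res = fit(D_clean, DeconvolutionConfig(k=5, n_inits=10, seed=5))
m = match_components(res.A_est, truth.A_true)
print(f"converged in {res.n_iter} iterations, objective {res.final_objective:.1f}")
print(f"matched MAE  : {mae(res.A_est, truth.A_true, m):.4f}")
print(f"matched RMSE : {rmse(res.A_est, truth.A_true, m):.4f}")
```

Output:

```
removed 1203 confounder-associated probes, kept 8797
K_hat raw     : 6
K_hat filtered: 5
converged in 68 iterations, objective 14658.2
matched MAE  : 0.0477
matched RMSE : 0.0630
```

Read it as a miniature study: with confounders left in, the scree rule
sees an extra mixture dimension (the sex effect alone is rank one) and
over-estimates K as 6; after removing ~1200 confounder-associated probes
it recovers the true K = 5, and the factorization then estimates each
sample's five cell-type fractions to within ~0.05 absolute error on
average.

## Command line

The same stages are exposed as subcommands over TSV/YAML files:

```bash
methdeconv simulate   --n-samples 100 --k 5 --n-probes 10000 --seed 1 --out-dir sim/
methdeconv preprocess --matrix sim/D.tsv --metadata sim/metadata.tsv --out-dir filt/
methdeconv select-k   --matrix filt/D_filtered.tsv --method cattell --out-dir k/
methdeconv deconvolve --matrix filt/D_filtered.tsv --k 5 --n-inits 10 --seed 5 --out-dir fit/
methdeconv evaluate   --a-est fit/A_est.tsv --a-true sim/A.tsv --out-dir eval/
methdeconv pipeline   --config config.yaml --out-dir run/     # all of the above
methdeconv benchmark  --spec grid.yaml --out results.tsv      # parameter sweeps
```

Matrices are plain TSV (probes × samples, `probe_id` first column);
missing values are rejected with the offending cell named.

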