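"""Probe filtering before deconvolution.

Confounder-associated probes (sex, age, batch, ...) carry variation that is
not driven by cell-type composition; leaving them in inflates the apparent
dimensionality of the mixture and distorts the factorization.  The main
filter regresses every probe on each measured covariate, applies
Benjamini-Hochberg FDR correction across probes per covariate, and removes
the union of significant probes.

Three optional feature-selection filters are also provided: high-variance
probes, probes correlated with the leading principal components, and
cell-type "informative loci" derived from reference profiles by
one-vs-rest (and pairwise) differential testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fixtures import CellTypeProfiles, CohortMetadata
from .simulate import BetaMatrix

__all__ = [
    "ProbeFilterResult",
    "benjamini_hochberg",
    "remove_confounded_probes",
    "fs_variance",
    "fs_pca",
    "fs_informative_loci",
]

logger = logging.getLogger(__name__)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR q-values)."""
    _, q, _, _ = multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")
    return q


@dataclass
class ProbeFilterResult:
    """Outcome of a probe filter: kept/removed partition plus statistics."""

    kept_probe_ids: list[str]
    removed_probe_ids: list[str]
    method: str
    stats: pd.DataFrame  # indexed by probe id; filter-specific columns + 'kept'
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        kept, removed = set(self.kept_probe_ids), set(self.removed_probe_ids)
        if kept & removed:
            raise ValueError("kept and removed probe sets overlap")

    @property
    def n_kept(self) -> int:
        return len(self.kept_probe_ids)

    @property
    def n_removed(self) -> int:
        return len(self.removed_probe_ids)

    def apply(self, D: BetaMatrix) -> BetaMatrix:
        """Row-select the kept probes from ``D`` (values untouched)."""
        return D.subset_probes(self.kept_probe_ids)

    def to_tsv(self, path) -> None:
        self.stats.to_csv(path, sep="\t", index_label="probe_id")


def _pearson_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided p-value of the slope of beta ~ covariate, per probe row.

    Identical to the t-test on the Pearson correlation with N-2 degrees of
    freedom.  Zero-variance probes get p = 1.
    """
    n = X.shape[1]
    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / denom
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[denom == 0] = 1.0
    p[sx == 0] = 1.0
    return p


def _anova_pvalues(X: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """One-way ANOVA F-test p-value per probe row for a categorical covariate."""
    n = X.shape[1]
    labels, inv = np.unique(groups, return_inverse=True)
    g = len(labels)
    grand = X.mean(axis=1, keepdims=True)
    sst = ((X - grand) ** 2).sum(axis=1)
    ssb = np.zeros(X.shape[0])
    for j in range(g):
        cols = inv == j
        nj = cols.sum()
        ssb += nj * (X[:, cols].mean(axis=1) - grand[:, 0]) ** 2
    ssw = np.maximum(sst - ssb, 0.0)
    df1, df2 = g - 1, n - g
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / np.maximum(ssw / df2, 1e-300)
    p = stats.f.sf(f, df1, df2)
    p[sst == 0] = 1.0
    return p


def remove_confounded_probes(
    D: BetaMatrix,
    metadata: CohortMetadata,
    covariates: list[str],
    fdr_q: float = 0.15,
) -> ProbeFilterResult:
    """Remove probes associated with any measured confounder.

    For each covariate a per-probe single-covariate test is run (slope
    t-test for numeric covariates, one-way ANOVA for categorical ones such
    as plate), p-values are Benjamini-Hochberg adjusted across all probes
    within that covariate, and probes with adjusted p <= ``fdr_q`` are
    flagged.  The removed set is the union of flags over covariates.
    """
    if D.n_samples < 3:
        raise ValueError("need at least 3 samples for per-probe regression")
    missing = [c for c in covariates if c not in metadata.table.columns]
    if missing:
        raise ValueError(f"covariate(s) {missing} not in metadata")
    if not 0 < fdr_q < 1:
        raise ValueError("fdr_q must be in (0, 1)")

    X = D.values
    stats_frame = pd.DataFrame(index=pd.Index(D.probe_ids, name="probe_id"))
    removed_mask = np.zeros(D.n_probes, dtype=bool)
    for cov in covariates:
        y = metadata[cov]
        if y.nunique() <= 1:
            logger.warning("covariate %r is constant; skipped", cov)
            continue
        if pd.api.types.is_numeric_dtype(y):
            p = _pearson_pvalues(X, y.to_numpy(dtype=float))
        else:
            p = _anova_pvalues(X, y.to_numpy())
        q = benjamini_hochberg(p)
        stats_frame[f"p_{cov}"] = p
        stats_frame[f"q_{cov}"] = q
        removed_mask |= q <= fdr_q

    stats_frame["kept"] = ~removed_mask
    probe_arr = np.asarray(D.probe_ids, dtype=object)
    return ProbeFilterResult(
        kept_probe_ids=list(probe_arr[~removed_mask]),
        removed_probe_ids=list(probe_arr[removed_mask]),
        method="confounder_regression",
        stats=stats_frame,
        params={"covariates": list(covariates), "fdr_q": fdr_q},
    )


def fs_variance(D: BetaMatrix, threshold: float = 0.02) -> ProbeFilterResult:
    """Keep probes whose across-sample variance exceeds ``threshold`` (strict)."""
    if D.n_samples < 2:
        raise ValueError("need at least 2 samples to compute variance")
    var = D.values.var(axis=1, ddof=1)
    keep = var > threshold
    probe_arr = np.asarray(D.probe_ids, dtype=object)
    stats_frame = pd.DataFrame(
        {"variance": var, "kept": keep}, index=pd.Index(D.probe_ids, name="probe_id")
    )
    return ProbeFilterResult(
        kept_probe_ids=list(probe_arr[keep]),
        removed_probe_ids=list(probe_arr[~keep]),
        method="variance",
        stats=stats_frame,
        params={"threshold": threshold},
    )


def fs_pca(
    D: BetaMatrix,
    n_pcs: int = 4,
    p_threshold: float = 0.1,
    mode: str = "any",
) -> ProbeFilterResult:
    """Keep probes significantly correlated with the leading sample-space PCs.

    The matrix is probe-centered (row means removed, no scaling), the first
    ``n_pcs`` principal-component score vectors are extracted, and each
    probe is tested for Pearson correlation against each score vector
    (two-sided t-test on r, N-2 df).  ``mode='any'`` (default) keeps probes
    significant for at least one PC; ``mode='all'`` requires all PCs.
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if D.n_samples <= n_pcs:
        raise ValueError("need more samples than principal components")
    xc = D.values - D.values.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    scores = vt[:n_pcs]  # (n_pcs, N)
    pmat = np.column_stack([_pearson_pvalues(D.values, s) for s in scores])
    nonconstant = D.values.var(axis=1) > 0
    if mode == "any":
        keep = (pmat < p_threshold).any(axis=1)
    elif mode == "all":
        keep = (pmat < p_threshold).all(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep &= nonconstant
    probe_arr = np.asarray(D.probe_ids, dtype=object)
    stats_frame = pd.DataFrame(
        pmat,
        columns=[f"p_pc{i + 1}" for i in range(n_pcs)],
        index=pd.Index(D.probe_ids, name="probe_id"),
    )
    stats_frame["kept"] = keep
    return ProbeFilterResult(
        kept_probe_ids=list(probe_arr[keep]),
        removed_probe_ids=list(probe_arr[~keep]),
        method="pca_correlation",
        stats=stats_frame,
        params={"n_pcs": n_pcs, "p_threshold": p_threshold, "mode": mode},
    )


def _welch_or_meandiff(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Welch t-test per probe row; mean-difference fallback for singleton groups.

    Returns (p_values, |mean difference|).  When either side has a single
    profile the test is impossible and p is NaN; callers then rank by the
    absolute mean difference.
    """
    diff = np.abs(a.mean(axis=1) - b.mean(axis=1))
    if a.shape[1] < 2 or b.shape[1] < 2:
        logger.warning("group with a single profile: ranking by |mean difference|")
        return np.full(a.shape[0], np.nan), diff
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.nan_to_num(res.pvalue, nan=1.0)
    return p, diff


def fs_informative_loci(
    references: CellTypeProfiles,
    group_labels: list[str],
    n_top: int = 500,
    n_pairwise: int = 100,
    p_threshold: float = 1e-4,
    pairs: list[tuple[str, str]] | None = None,
) -> ProbeFilterResult:
    """Select cell-type informative loci from grouped reference profiles.

    One-vs-rest differential tests per probe per reference group; the
    ``n_top`` most significant probes passing ``p_threshold`` (ranked by
    minimum p over groups) are retained.  For each requested pair of groups
    the ``n_pairwise`` most significant pairwise-test probes are added.
    The result is the union of unique probe ids.
    """
    labels = np.asarray(group_labels)
    if len(labels) != references.n_types:
        raise ValueError("group_labels must have one entry per reference column")
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least 2 reference groups")

    X = references.values
    m = references.n_probes
    min_p = np.full(m, np.inf)
    max_diff = np.zeros(m)
    for g in groups:
        in_g = labels == g
        p, diff = _welch_or_meandiff(X[:, in_g], X[:, ~in_g])
        min_p = np.fmin(min_p, p)  # fmin ignores NaN from singleton groups
        max_diff = np.maximum(max_diff, diff)

    if np.all(np.isinf(min_p)) or np.all(np.isnan(min_p)):
        passing = np.argsort(-max_diff)[:n_top]
    else:
        ok = np.flatnonzero(min_p < p_threshold)
        passing = ok[np.argsort(min_p[ok], kind="stable")][:n_top]
    selected = set(np.asarray(references.probe_ids, dtype=object)[passing])

    probe_arr = np.asarray(references.probe_ids, dtype=object)
    for pair in pairs or []:
        ga, gb = pair
        for g in (ga, gb):
            if g not in groups:
                raise ValueError(f"unknown reference group {g!r}")
        p, diff = _welch_or_meandiff(X[:, labels == ga], X[:, labels == gb])
        if np.all(np.isnan(p)):
            order = np.argsort(-diff)
        else:
            order = np.argsort(p, kind="stable")
        selected |= set(probe_arr[order[:n_pairwise]])

    keep_mask = np.isin(probe_arr, list(selected))
    stats_frame = pd.DataFrame(
        {"min_p_one_vs_rest": min_p, "max_abs_mean_diff": max_diff, "kept": keep_mask},
        index=pd.Index(references.probe_ids, name="probe_id"),
    )
    return ProbeFilterResult(
        kept_probe_ids=list(probe_arr[keep_mask]),
        removed_probe_ids=list(probe_arr[~keep_mask]),
        method="informative_loci",
        stats=stats_frame,
        params={
            "n_top": n_top,
            "n_pairwise": n_pairwise,
            "p_threshold": p_threshold,
            "pairs": [list(p) for p in (pairs or [])],
        },
    )
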