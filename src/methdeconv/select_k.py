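"""Choosing the number of cell types K.

Three complementary routes:

* **Scree / Cattell's rule** -- eigenvalues of the probe-centered sample
  covariance in descending order.  A noiseless K-type mixture with
  sum-to-one proportions spans an affine subspace of dimension K-1, so
  K-1 eigenvalues stand above the noise floor and the estimate is
  K = retained PCs + 1.  The visual elbow reading is automated with a
  chord rule: the elbow is the component with maximum vertical gap below
  the straight line joining the first and last plotted eigenvalues.
* **Subset stability** -- refit on random 80% sample subsets and keep the
  largest K whose matched components agree across subsets.
* **Leave-columns-out cross-validation** -- fit T on training samples,
  estimate A on held-out samples with T fixed, and score the held-out
  reconstruction error over a (K, lambda) grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from . import evaluate as ev
from .model import DeconvolutionConfig, fit, fit_A_given_T
from .simulate import BetaMatrix, ProportionMatrix

__all__ = [
    "ScreeResult",
    "StabilityResult",
    "scree_eigenvalues",
    "cattell_k",
    "stability_k",
    "cv_select",
]

logger = logging.getLogger(__name__)


@dataclass
class ScreeResult:
    """Eigenvalue spectrum and (after elbow detection) the K estimate."""

    eigenvalues: np.ndarray  # descending, nonnegative
    retained_pcs: int | None = None
    k_hat: int | None = None
    gaps: np.ndarray | None = None  # vertical chord gaps, elbow diagnostics

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be sorted in descending order")
        if self.k_hat is not None and self.retained_pcs is not None:
            if self.k_hat != self.retained_pcs + 1:
                raise ValueError("k_hat must equal retained_pcs + 1")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "component": np.arange(1, len(self.eigenvalues) + 1),
                "eigenvalue": self.eigenvalues,
            }
        )
        if self.gaps is not None:
            gaps = np.full(len(self.eigenvalues), np.nan)
            gaps[: len(self.gaps)] = self.gaps
            frame["chord_gap"] = gaps
        return frame


@dataclass
class StabilityResult:
    candidate_ks: list[int]
    t_scores: dict[int, float]
    a_scores: dict[int, float]
    chosen_k: int | None
    threshold: float


def scree_eigenvalues(D: BetaMatrix) -> ScreeResult:
    """Eigenvalues of the sample covariance of the probe-centered matrix."""
    if D.n_samples < 2:
        raise ValueError("need at least 2 samples")
    xc = D.values - D.values.mean(axis=1, keepdims=True)
    s = np.linalg.svd(xc, compute_uv=False)
    eig = (s**2) / (D.n_samples - 1)
    return ScreeResult(eigenvalues=eig)


def cattell_k(
    scree: ScreeResult, max_components: int = 30, tol: float = 1e-8
) -> ScreeResult:
    """Automated Cattell elbow: maximum vertical gap below the scree chord.

    Over components 1..L (L = min(max_components, available)), draw the
    chord from (1, ev_1) to (L, ev_L); the elbow is the component with the
    largest vertical gap below the chord.  Retained PCs = elbow - 1 and
    the estimate is K = retained PCs + 1.  If no gap exceeds
    ``tol * ev_1`` (e.g. strictly linear decay) there is no elbow and
    ``k_hat`` is None.
    """
    ev_all = scree.eigenvalues
    if len(ev_all) < 3:
        raise ValueError("need at least 3 eigenvalues for elbow detection")
    L = min(max_components, len(ev_all))
    evs = ev_all[:L]
    idx = np.arange(L, dtype=float)
    chord = evs[0] + (evs[L - 1] - evs[0]) * idx / (L - 1)
    gaps = chord - evs  # positive where the scree dips below the chord
    scale = max(abs(evs[0]), 1e-300)
    if gaps.max() <= tol * scale:
        return dc_replace(scree, retained_pcs=None, k_hat=None, gaps=gaps)
    elbow = int(np.argmax(gaps)) + 1  # 1-based component index
    return dc_replace(scree, retained_pcs=elbow - 1, k_hat=elbow, gaps=gaps)


def _pairwise_pearson(cols_a: np.ndarray, cols_b: np.ndarray) -> float:
    """Mean Pearson correlation of paired columns of two equally-shaped matrices."""
    rs = []
    for x, y in zip(cols_a.T, cols_b.T):
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        rs.append(float(np.corrcoef(x, y)[0, 1]))
    return float(np.mean(rs)) if rs else np.nan


def stability_k(
    D: BetaMatrix,
    candidate_ks: list[int],
    n_subsets: int = 3,
    subset_frac: float = 0.8,
    config: DeconvolutionConfig | None = None,
    threshold: float = 0.9,
    seed: int = 0,
) -> StabilityResult:
    """EDec-style stability: refit on random sample subsets and compare estimates.

    For each candidate K the deconvolution is run on ``n_subsets`` random
    ``subset_frac`` subsets of samples; after matched-component alignment
    (by proportion rows on shared samples) the stability score is the mean
    pairwise Pearson correlation of matched T columns (and of matched A
    rows on shared samples).  The chosen K is the largest candidate whose
    two scores both exceed ``threshold``.
    """
    if n_subsets < 2:
        raise ValueError("pairwise similarity needs n_subsets >= 2")
    if min(candidate_ks) < 2:
        raise ValueError("candidate Ks must be >= 2")
    rng = np.random.default_rng(seed)
    n = D.n_samples
    size = max(2, int(round(subset_frac * n)))
    subsets = [np.sort(rng.choice(n, size=size, replace=False)) for _ in range(n_subsets)]
    sample_arr = np.asarray(D.sample_ids, dtype=object)

    t_scores: dict[int, float] = {}
    a_scores: dict[int, float] = {}
    for k in candidate_ks:
        if size < k:
            logger.warning("subset size %d too small for K=%d; skipped", size, k)
            continue
        base = config or DeconvolutionConfig(k=k)
        cfg = dc_replace(base, k=k)
        fits = []
        for s_idx, cols in enumerate(subsets):
            sub = BetaMatrix(
                list(D.probe_ids), list(sample_arr[cols]), D.values[:, cols]
            )
            fits.append((cols, fit(sub, dc_replace(cfg, seed=cfg.seed + 1000 * s_idx))))
        t_pair, a_pair = [], []
        for i in range(n_subsets):
            for j in range(i + 1, n_subsets):
                cols_i, fit_i = fits[i]
                cols_j, fit_j = fits[j]
                shared = np.intersect1d(cols_i, cols_j)
                if len(shared) < 3:
                    continue
                pos_i = np.searchsorted(cols_i, shared)
                pos_j = np.searchsorted(cols_j, shared)
                a_i = ProportionMatrix(
                    fit_i.A_est.type_names,
                    list(sample_arr[shared]),
                    fit_i.A_est.values[:, pos_i],
                    constraint_mode=fit_i.A_est.constraint_mode,
                )
                a_j = ProportionMatrix(
                    fit_j.A_est.type_names,
                    list(sample_arr[shared]),
                    fit_j.A_est.values[:, pos_j],
                    constraint_mode=fit_j.A_est.constraint_mode,
                )
                match = ev.match_components(a_j, a_i)
                t_i = np.column_stack(
                    [fit_i.T_est.values[:, t] for t in match.mapping.keys()]
                )
                t_j = np.column_stack(
                    [fit_j.T_est.values[:, e] for e in match.mapping.values()]
                )
                t_pair.append(_pairwise_pearson(t_i, t_j))
                a_pair.append(
                    _pairwise_pearson(
                        a_i.values[list(match.mapping.keys())].T,
                        a_j.values[list(match.mapping.values())].T,
                    )
                )
        t_scores[k] = float(np.nanmean(t_pair)) if t_pair else np.nan
        a_scores[k] = float(np.nanmean(a_pair)) if a_pair else np.nan

    stable = [
        k
        for k in t_scores
        if np.isfinite(t_scores[k])
        and np.isfinite(a_scores[k])
        and t_scores[k] > threshold
        and a_scores[k] > threshold
    ]
    chosen = max(stable) if stable else None
    return StabilityResult(
        candidate_ks=list(candidate_ks),
        t_scores=t_scores,
        a_scores=a_scores,
        chosen_k=chosen,
        threshold=threshold,
    )


def cv_select(
    D: BetaMatrix,
    candidate_ks: list[int],
    lambdas: tuple[float, ...] = (0.0,),
    n_folds: int = 10,
    config: DeconvolutionConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-columns-out cross-validation error over a (K, lambda) grid.

    Samples are partitioned into ``n_folds`` folds; for each fold, T is
    fitted on the training columns and held-out columns are reconstructed
    through a fixed-T A-step.  CVE is the mean held-out squared error per
    matrix entry.  Returns a tidy table with columns K, lambda, cve.
    """
    n = D.n_samples
    if n < n_folds:
        raise ValueError("need at least n_folds samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    sample_arr = np.asarray(D.sample_ids, dtype=object)

    rows = []
    for k in candidate_ks:
        for lam in lambdas:
            base = config or DeconvolutionConfig(k=k)
            cfg = dc_replace(base, k=k, lam=lam)
            sq_err, n_entries = 0.0, 0
            for f_idx, test_cols in enumerate(folds):
                train_cols = np.setdiff1d(perm, test_cols)
                train = BetaMatrix(
                    list(D.probe_ids),
                    list(sample_arr[train_cols]),
                    D.values[:, train_cols],
                )
                test = BetaMatrix(
                    list(D.probe_ids),
                    list(sample_arr[test_cols]),
                    D.values[:, test_cols],
                )
                res = fit(train, dc_replace(cfg, seed=cfg.seed + 100 * f_idx))
                a_test = fit_A_given_T(test, res.T_est, cfg.constraint_mode)
                resid = test.values - res.T_est.values @ a_test.values
                sq_err += float(np.sum(resid**2))
                n_entries += resid.size
            rows.append({"K": k, "lambda": lam, "cve": sq_err / n_entries})
    return pd.DataFrame(rows)
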