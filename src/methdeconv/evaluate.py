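"""Scoring inferred proportions and profiles against ground truth.

Reference-free factorization recovers cell types only up to relabeling, so
all metrics are computed after matching: estimated components are paired
with true components by the injective assignment that minimizes the mean
absolute error of the paired proportion rows.  When the fitted K exceeds
the true K, surplus estimated components are simply left unpaired (the
pairing that minimizes MAE is retained); when it is smaller, a best subset
of true components is paired and the denominator counts paired types only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .fixtures import CellTypeProfiles
from .simulate import ProportionMatrix

__all__ = [
    "MatchResult",
    "EvaluationResult",
    "match_components",
    "mae",
    "rmse",
    "profile_correlation",
]

_BRUTE_FORCE_LIMIT = 8


@dataclass
class MatchResult:
    """Injective mapping true-type index -> estimated-type index."""

    mapping: dict[int, int]
    per_type_mae: dict[int, float]
    mae: float

    def __post_init__(self) -> None:
        if len(set(self.mapping.values())) != len(self.mapping):
            raise ValueError("mapping must be injective")


@dataclass
class EvaluationResult:
    mae: float
    rmse: float
    correlation: pd.DataFrame | None
    match: MatchResult


def _aligned_values(
    A_est: ProportionMatrix, A_true: ProportionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    if set(A_est.sample_ids) != set(A_true.sample_ids):
        raise ValueError("estimated and true proportion matrices share no common sample order")
    if list(A_est.sample_ids) == list(A_true.sample_ids):
        return A_est.values, A_true.values
    order = [A_est.sample_ids.index(s) for s in A_true.sample_ids]
    return A_est.values[:, order], A_true.values


def match_components(A_est: ProportionMatrix, A_true: ProportionMatrix) -> MatchResult:
    """Pair true and estimated components to minimize mean absolute error.

    The total cost decomposes over pairs, so the optimum is found by
    exhaustive search over injective maps for small K (with lexicographic
    tie-breaking) and by optimal linear assignment otherwise.
    """
    est, true = _aligned_values(A_est, A_true)
    k_true, k_est = true.shape[0], est.shape[0]
    n_pairs = min(k_true, k_est)
    # cost[i, j] = mean |est_j - true_i| over samples
    cost = np.abs(true[:, None, :] - est[None, :, :]).mean(axis=2)

    if n_pairs <= _BRUTE_FORCE_LIMIT:
        small_on_rows = k_true <= k_est
        big, small = (k_est, k_true) if small_on_rows else (k_true, k_est)
        best_cost, best_map = np.inf, None
        for combo in permutations(range(big), small):
            pairs = (
                [(i, j) for i, j in enumerate(combo)]
                if small_on_rows
                else [(i, j) for j, i in enumerate(combo)]
            )
            total = sum(cost[i, j] for i, j in pairs)
            if total < best_cost - 1e-15:
                best_cost, best_map = total, pairs
        mapping = dict(sorted(best_map))
    else:
        rows, cols = linear_sum_assignment(cost)
        mapping = dict(zip(rows.tolist(), cols.tolist()))

    per_type = {i: float(cost[i, j]) for i, j in mapping.items()}
    overall = float(np.mean(list(per_type.values())))
    return MatchResult(mapping=mapping, per_type_mae=per_type, mae=overall)


def mae(
    A_est: ProportionMatrix, A_true: ProportionMatrix, match: MatchResult | None = None
) -> float:
    """Matched mean absolute error: mean |A_est - A_true| over paired entries."""
    if match is None:
        match = match_components(A_est, A_true)
    if not match.mapping:
        raise ValueError("empty component pairing")
    est, true = _aligned_values(A_est, A_true)
    t_idx = list(match.mapping.keys())
    e_idx = [match.mapping[i] for i in t_idx]
    return float(np.abs(est[e_idx] - true[t_idx]).mean())


def rmse(
    A_est: ProportionMatrix, A_true: ProportionMatrix, match: MatchResult | None = None
) -> float:
    """Matched root-mean-square error over paired entries."""
    if match is None:
        match = match_components(A_est, A_true)
    if not match.mapping:
        raise ValueError("empty component pairing")
    est, true = _aligned_values(A_est, A_true)
    t_idx = list(match.mapping.keys())
    e_idx = [match.mapping[i] for i in t_idx]
    return float(np.sqrt(((est[e_idx] - true[t_idx]) ** 2).mean()))


def profile_correlation(T_est: CellTypeProfiles, T_ref: CellTypeProfiles) -> pd.DataFrame:
    """Pearson correlation of every (estimated, reference) profile column pair.

    Probe sets are intersected by id.  Constant columns yield NaN.
    """
    shared = [p for p in T_est.probe_ids if p in set(T_ref.probe_ids)]
    if not shared:
        raise ValueError("estimated and reference profiles share no probes")
    est = T_est.subset_probes(shared).values
    ref = T_ref.subset_probes(shared).values
    out = np.full((est.shape[1], ref.shape[1]), np.nan)
    ec = est - est.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    es = np.sqrt((ec**2).sum(axis=0))
    rs = np.sqrt((rc**2).sum(axis=0))
    # a constant column (zero variance up to rounding) has no correlation
    e_const = np.ptp(est, axis=0) == 0
    r_const = np.ptp(ref, axis=0) == 0
    for i in range(est.shape[1]):
        for j in range(ref.shape[1]):
            denom = es[i] * rs[j]
            if denom > 0 and not (e_const[i] or r_const[j]):
                out[i, j] = float(ec[:, i] @ rc[:, j] / denom)
    return pd.DataFrame(out, index=T_est.type_names, columns=T_ref.type_names)


def evaluate(
    A_est: ProportionMatrix,
    A_true: ProportionMatrix,
    T_est: CellTypeProfiles | None = None,
    T_ref: CellTypeProfiles | None = None,
) -> EvaluationResult:
    """Convenience wrapper: matching, MAE, RMSE and (optionally) T correlations."""
    match = match_components(A_est, A_true)
    corr = None
    if T_est is not None and T_ref is not None:
        corr = profile_correlation(T_est, T_ref)
    return EvaluationResult(
        mae=mae(A_est, A_true, match),
        rmse=rmse(A_est, A_true, match),
        correlation=corr,
        match=match,
    )
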