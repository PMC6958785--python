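"""Constrained matrix factorization for reference-free deconvolution.

The bulk beta matrix D (M probes x N samples) is modeled as D = TA with
T (M x K) the cell-type methylation profiles and A (K x N) the mixing
proportions.  Both factors are estimated by alternating minimization of

    || D - TA ||_F^2  +  lambda * sum_ij T_ij (1 - T_ij)

subject to 0 <= T <= 1 and per-column simplex constraints on A (sum equal
to 1, or at most 1 in the inequality variant).  The omega = t(1-t)
regularizer vanishes at 0 and 1, pushing inferred profiles toward the
biologically plausible methylation extremes.

The A-step solves each sample's simplex-constrained least-squares problem
exactly by an active-set method; the T-step runs cyclic coordinate descent
on each probe row's box-constrained quadratic (exact 1-D minimizers, so the
objective never increases; with lambda above the curvature of A A^T the 1-D
pieces turn concave and the update selects the better endpoint, yielding a
stationary point).

Initialization follows the three families in common use: random Dirichlet
proportions (A-side), hierarchical clustering of samples (T-side), and
median-binarized truncated SVD (T-side), plus a user-supplied T.  Multi-start
keeps the lowest-objective run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .fixtures import CellTypeProfiles
from .simulate import BetaMatrix, ProportionMatrix

__all__ = [
    "DeconvolutionConfig",
    "FitResult",
    "objective",
    "update_A",
    "update_T",
    "init_A_dirichlet",
    "init_T_cluster",
    "init_T_svd",
    "fit",
    "fit_A_given_T",
    "LAMBDA_GRID",
]

logger = logging.getLogger(__name__)

#: default regularization grid
LAMBDA_GRID = (0.0, 1e-5, 1e-4, 1e-3, 1e-2, 0.1)

_KKT_TOL = 1e-8


@dataclass
class DeconvolutionConfig:
    """Settings for one deconvolution run."""

    k: int
    lam: float = 0.0
    constraint_mode: str = "sum-to-one"
    init: str = "dirichlet-A"  # dirichlet-A | cluster-T | svd-T | given-T
    init_distance: str = "euclidean"
    init_linkage: str = "ward"
    T0: np.ndarray | None = None  # for init = given-T
    n_inits: int = 10
    max_iter: int = 300
    rel_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.n_inits < 1:
            raise ValueError("n_inits must be >= 1")
        if self.constraint_mode not in ("sum-to-one", "sum-at-most-one"):
            raise ValueError(f"unknown constraint_mode {self.constraint_mode!r}")
        if self.init not in ("dirichlet-A", "cluster-T", "svd-T", "given-T"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.init == "given-T" and self.T0 is None:
            raise ValueError("init='given-T' requires T0")


@dataclass
class FitResult:
    """Estimated factors plus optimization diagnostics for the winning restart."""

    T_est: CellTypeProfiles
    A_est: ProportionMatrix
    objectives: list[float]
    final_objective: float
    n_iter: int
    converged: bool
    init: str
    seed: int
    restart_objectives: list[float] = field(default_factory=list)


def objective(D: np.ndarray, T: np.ndarray, A: np.ndarray, lam: float = 0.0) -> float:
    """Squared Frobenius reconstruction error plus the omega penalty on T."""
    if T.shape[1] != A.shape[0] or D.shape != (T.shape[0], A.shape[1]):
        raise ValueError("D, T, A shapes are not conformable")
    resid = D - T @ A
    val = float(np.sum(resid * resid))
    if lam:
        val += lam * float(np.sum(T * (1.0 - T)))
    return val


def _solve_simplex_columns(
    G: np.ndarray, H: np.ndarray, inequality: bool, tol: float = _KKT_TOL
) -> np.ndarray:
    """Minimize a'Ga - 2 h'a per column of H subject to a >= 0 and 1'a = 1.

    Active-set iterations run synchronously over columns, grouped by the
    pattern of zeroed variables so each distinct KKT system is factorized
    once per round.  The inequality variant (1'a <= 1) is handled by an
    explicit slack variable appended as a zero row/column of G.
    """
    if inequality:
        k = G.shape[0]
        G2 = np.zeros((k + 1, k + 1))
        G2[:k, :k] = G
        H2 = np.vstack([H, np.zeros((1, H.shape[1]))])
        return _solve_simplex_columns(G2, H2, False, tol)[:k]

    k, n = H.shape
    free = np.ones((k, n), dtype=bool)
    A = np.full((k, n), 1.0 / k)
    max_rounds = 4 * k + 8
    for _ in range(max_rounds):
        changed = False
        patterns: dict[bytes, list[int]] = {}
        for j in range(n):
            patterns.setdefault(free[:, j].tobytes(), []).append(j)
        for pat, cols in patterns.items():
            f = np.frombuffer(pat, dtype=bool)
            nf = int(f.sum())
            cols_arr = np.asarray(cols)
            if nf == 0:  # everything clamped: restart fully free
                free[:, cols_arr] = True
                changed = True
                continue
            kkt = np.zeros((nf + 1, nf + 1))
            kkt[:nf, :nf] = 2.0 * G[np.ix_(f, f)]
            kkt[:nf, nf] = 1.0
            kkt[nf, :nf] = 1.0
            rhs = np.vstack([2.0 * H[f][:, cols_arr], np.ones((1, len(cols)))])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
            a_f = sol[:nf]  # (nf, len(cols))
            nu = sol[nf]  # (len(cols),)
            # primal check: clamp the most negative free variable
            min_idx = np.argmin(a_f, axis=0)
            min_val = a_f[min_idx, np.arange(len(cols))]
            neg = min_val < -tol
            if np.any(neg):
                bad = cols_arr[neg]
                free[np.flatnonzero(f)[min_idx[neg]], bad] = False
                changed = True
            ok = cols_arr[~neg]
            if len(ok):
                a_full = np.zeros((k, len(ok)))
                a_full[f] = np.clip(a_f[:, ~neg], 0.0, None)
                A[:, ok] = a_full
                # dual check: release a clamped variable with negative multiplier
                if (~f).any():
                    grad = 2.0 * (G @ a_full - H[:, ok])
                    mu = grad[~f] + nu[~neg][None, :]
                    worst = np.argmin(mu, axis=0)
                    viol = mu[worst, np.arange(len(ok))] < -tol
                    if np.any(viol):
                        free[np.flatnonzero(~f)[worst[viol]], ok[viol]] = True
                        changed = True
        if not changed:
            break
    else:
        logger.warning("active-set solver hit its round cap; returning projected iterate")
    A = np.clip(A, 0.0, 1.0)
    sums = A.sum(axis=0)
    fix = sums > 0
    A[:, fix] /= sums[fix]
    return A


def update_A(D: np.ndarray, T: np.ndarray, constraint_mode: str = "sum-to-one") -> np.ndarray:
    """Exact per-column simplex-constrained least squares: argmin_A ||D - TA||^2."""
    if D.shape[0] != T.shape[0]:
        raise ValueError("D and T probe dimensions differ")
    G = T.T @ T
    H = T.T @ D
    return _solve_simplex_columns(G, H, inequality=(constraint_mode == "sum-at-most-one"))


def update_T(
    D: np.ndarray,
    A: np.ndarray,
    lam: float = 0.0,
    T_init: np.ndarray | None = None,
    max_sweeps: int = 100,
    tol: float = 1e-9,
) -> np.ndarray:
    """Box-constrained T-step by cyclic coordinate descent over type columns.

    Each probe row minimizes ||d - tA||^2 + lambda * sum_k t_k (1 - t_k)
    over t in [0,1]^K.  All rows share the A A' Gram matrix, so every 1-D
    update is vectorized across the M rows.  Each 1-D update is exact
    (interior clip for the convex case, best endpoint for the concave
    case), so the row objectives never increase.
    """
    if D.shape[1] != A.shape[1]:
        raise ValueError("D and A sample dimensions differ")
    m, k = D.shape[0], A.shape[0]
    AAt = A @ A.T
    DAt = D @ A.T
    T = np.full((m, k), 0.5) if T_init is None else np.clip(T_init, 0.0, 1.0).copy()
    diag = np.diag(AAt)
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(k):
            # linear coefficient of the 1-D problem in t_j
            cross = T @ AAt[:, j] - T[:, j] * diag[j]
            numer = DAt[:, j] - cross - lam / 2.0
            c2 = diag[j] - lam
            if c2 > 1e-12:
                t_new = np.clip(numer / c2, 0.0, 1.0)
            else:
                # concave or flat 1-D piece: compare endpoint objectives
                t_new = np.where(c2 - 2.0 * numer < 0.0, 1.0, 0.0)
            delta = np.abs(t_new - T[:, j])
            if delta.size:
                max_delta = max(max_delta, float(delta.max()))
            T[:, j] = t_new
        if max_delta < tol:
            break
    return T


def init_A_dirichlet(n_samples: int, k: int, seed: int = 0) -> np.ndarray:
    """Random proportions: columns drawn from a flat Dirichlet(1, ..., 1)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(k), size=n_samples).T


def init_T_cluster(
    D: np.ndarray, k: int, distance: str = "euclidean", linkage_method: str = "ward"
) -> np.ndarray:
    """Initial T from hierarchical clustering of the sample columns.

    Samples are clustered under the chosen distance/linkage, the tree is
    cut into K clusters, and each initial T column is the mean methylation
    profile of one cluster.
    """
    n = D.shape[1]
    if n < k:
        raise ValueError("need at least K samples to form K clusters")
    metric = {"euclidean": "euclidean", "manhattan": "cityblock"}.get(distance)
    if metric is None:
        raise ValueError(f"unknown distance {distance!r}")
    if linkage_method == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean distance")
    Z = linkage(pdist(D.T, metric=metric), method=linkage_method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    cols = []
    for lab in range(1, labels.max() + 1):
        members = labels == lab
        if members.any():
            cols.append(D[:, members].mean(axis=1))
    T = np.column_stack(cols)
    if T.shape[1] < k:  # degenerate cut: pad with duplicated columns
        extra = k - T.shape[1]
        T = np.column_stack([T] + [T[:, -1]] * extra)
    return T


def init_T_svd(D: np.ndarray, k: int) -> np.ndarray:
    """Initial T from the first K left singular vectors, median-binarized per row.

    Entries >= their row median become 1, the rest 0, so the initial T is
    binary and carries zero omega penalty.
    """
    if k > min(D.shape):
        raise ValueError("k cannot exceed min(M, N)")
    U, _, _ = np.linalg.svd(D, full_matrices=False)
    Uk = U[:, :k]
    med = np.median(Uk, axis=1, keepdims=True)
    return (Uk >= med).astype(float)


def _initial_factors(
    D: np.ndarray, config: DeconvolutionConfig, restart_seed: int
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Return (T0, A0); exactly one is set, determining which update runs first."""
    if config.init == "dirichlet-A":
        return None, init_A_dirichlet(D.shape[1], config.k, restart_seed)
    if config.init == "cluster-T":
        return init_T_cluster(D, config.k, config.init_distance, config.init_linkage), None
    if config.init == "svd-T":
        return init_T_svd(D, config.k), None
    return np.clip(np.asarray(config.T0, dtype=float), 0.0, 1.0), None


def _alternate(
    D: np.ndarray, config: DeconvolutionConfig, restart_seed: int
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    T0, A0 = _initial_factors(D, config, restart_seed)
    if T0 is not None:
        T = T0
        A = update_A(D, T, config.constraint_mode)
    else:
        A = A0
        T = update_T(D, A, config.lam)
        A = update_A(D, T, config.constraint_mode)
    objectives = [objective(D, T, A, config.lam)]
    converged = False
    for _ in range(config.max_iter):
        T = update_T(D, A, config.lam, T_init=T)
        A = update_A(D, T, config.constraint_mode)
        objectives.append(objective(D, T, A, config.lam))
        prev, cur = objectives[-2], objectives[-1]
        if abs(prev - cur) <= config.rel_tol * max(abs(prev), 1e-12):
            converged = True
            break
    return T, A, objectives, converged


def fit(D: BetaMatrix, config: DeconvolutionConfig) -> FitResult:
    """Multi-start alternating minimization; returns the lowest-objective run.

    Restart seeds are ``config.seed + i``.  Only the Dirichlet-A
    initialization is stochastic; for the deterministic initializations a
    single start is run.
    """
    values = D.values
    if np.any(~np.isfinite(values)):
        raise ValueError("D contains non-finite values")
    if values.min() < 0 or values.max() > 1:
        raise ValueError("D entries must lie in [0, 1]")
    if config.k > min(values.shape):
        raise ValueError("k cannot exceed min(M, N)")

    n_starts = config.n_inits if config.init == "dirichlet-A" else 1
    best = None
    restart_objectives = []
    for i in range(n_starts):
        restart_seed = config.seed + i
        T, A, objectives, converged = _alternate(values, config, restart_seed)
        restart_objectives.append(objectives[-1])
        if best is None or objectives[-1] < best[2][-1]:
            best = (T, A, objectives, converged, restart_seed)

    T, A, objectives, converged, restart_seed = best
    type_names = [f"est_{i + 1}" for i in range(config.k)]
    t_est = CellTypeProfiles(list(D.probe_ids), type_names, np.clip(T, 0.0, 1.0))
    a_est = ProportionMatrix(
        type_names, list(D.sample_ids), A, constraint_mode=config.constraint_mode
    )
    return FitResult(
        T_est=t_est,
        A_est=a_est,
        objectives=[float(o) for o in objectives],
        final_objective=float(objectives[-1]),
        n_iter=len(objectives) - 1,
        converged=converged,
        init=config.init,
        seed=restart_seed,
        restart_objectives=[float(o) for o in restart_objectives],
    )


def fit_A_given_T(
    D: BetaMatrix, T: CellTypeProfiles, constraint_mode: str = "sum-to-one"
) -> ProportionMatrix:
    """Single constrained A-step with a fixed profile matrix.

    Used by leave-columns-out cross-validation and by reference-anchored
    proportion estimation.  Probe sets are intersected by id.
    """
    shared = [p for p in D.probe_ids if p in set(T.probe_ids)]
    if not shared:
        raise ValueError("D and T share no probes")
    d_sub = D.subset_probes(shared)
    t_sub = T.subset_probes(shared)
    A = update_A(d_sub.values, t_sub.values, constraint_mode)
    return ProportionMatrix(
        list(T.type_names), list(D.sample_ids), A, constraint_mode=constraint_mode
    )
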