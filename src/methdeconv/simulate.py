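"""Ground-truthed simulation of heterogeneous-tissue methylation matrices.

The generative model is D = TA: per-sample mixing proportions A are drawn
from a Dirichlet distribution, each individual's cell-type profile matrix T
is perturbed by sex and age effects, the bulk matrix is formed by convex
mixing, and technical artefacts are added (multiplicative plate effects,
then Gaussian noise with a skip-at-boundary rule: a noise draw that would
push a beta value outside [0, 1] is discarded and the value kept as is,
rather than clamped).

Stage order: sex -> age -> mix -> plate -> noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .fixtures import (
    DEFAULT_TYPE_NAMES,
    CellTypeProfiles,
    CohortMetadata,
    ConfounderEffects,
)

__all__ = [
    "SimulationConfig",
    "ProportionMatrix",
    "BetaMatrix",
    "IndividualProfiles",
    "SimulationTruth",
    "simulate_proportions",
    "tile_profiles",
    "apply_sex_effect",
    "apply_age_effect",
    "mix",
    "apply_plate_effect",
    "add_noise",
    "simulate_dataset",
    "DEFAULT_BASE_PROPS",
]

#: default mixing proportions: (fibroblast, cancer epithelial, T lymphocyte,
#: control epithelial, cancer mesenchymal) for the 5-type background and
#: (fibroblast, cancer epithelial, T lymphocyte) for the 3-type variant.
DEFAULT_BASE_PROPS = {
    5: (0.10, 0.60, 0.05, 0.15, 0.10),
    3: (0.20, 0.70, 0.10),
}

_SUM_TOL = 1e-8


@dataclass
class SimulationConfig:
    """Parameters of one simulated cohort.

    alpha0 scales the Dirichlet concentration (concentration vector =
    ``alpha0 * base_props``): small alpha0 (~1) gives diverse proportions
    across samples, large alpha0 concentrates every sample at
    ``base_props``.  epsilon is the standard deviation of the final
    Gaussian noise stage.
    """

    n_samples: int
    n_types: int
    alpha0: float = 1.0
    base_props: tuple[float, ...] | None = None
    epsilon: float = 0.2
    background: str = "G1"
    seed: int = 0
    plate_before_noise: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_types < 1:
            raise ValueError("n_samples and n_types must be positive")
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.base_props is None:
            default = DEFAULT_BASE_PROPS.get(self.n_types)
            if default is None:
                default = tuple(1.0 / self.n_types for _ in range(self.n_types))
            self.base_props = default
        self.base_props = tuple(float(p) for p in self.base_props)
        if len(self.base_props) != self.n_types:
            raise ValueError("base_props length must equal n_types")
        if any(p <= 0 for p in self.base_props):
            raise ValueError("base_props must be strictly positive")
        if abs(sum(self.base_props) - 1.0) > _SUM_TOL:
            raise ValueError("base_props must sum to 1")

    def to_yaml(self, path) -> None:
        payload = {
            "n_samples": self.n_samples,
            "n_types": self.n_types,
            "alpha0": float(self.alpha0),
            "base_props": list(self.base_props),
            "epsilon": float(self.epsilon),
            "background": self.background,
            "seed": int(self.seed),
            "plate_before_noise": bool(self.plate_before_noise),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["base_props"] = tuple(payload["base_props"]) if payload.get("base_props") else None
        return cls(**payload)


@dataclass
class ProportionMatrix:
    """Cell-types x samples matrix of mixing proportions (the A matrix)."""

    type_names: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (K, N)
    constraint_mode: str = "sum-to-one"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k, n = self.values.shape
        if len(self.type_names) != k or len(self.sample_ids) != n:
            raise ValueError("id lists inconsistent with value matrix shape")
        if self.values.min() < -_SUM_TOL or self.values.max() > 1 + _SUM_TOL:
            raise ValueError("proportions must lie in [0, 1]")
        sums = self.values.sum(axis=0)
        if self.constraint_mode == "sum-to-one":
            if np.any(np.abs(sums - 1.0) > _SUM_TOL):
                raise ValueError("proportion columns must sum to 1")
        elif self.constraint_mode == "sum-at-most-one":
            if np.any(sums > 1 + _SUM_TOL):
                raise ValueError("proportion column sums must be <= 1")
        elif self.constraint_mode != "none":  # "none": box constraint only
            raise ValueError(f"unknown constraint_mode {self.constraint_mode!r}")

    @property
    def n_types(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.type_names, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kw) -> "ProportionMatrix":
        return cls(
            type_names=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            **kw,
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="cell_type")

    @classmethod
    def from_tsv(cls, path, **kw) -> "ProportionMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0), **kw)


@dataclass
class BetaMatrix:
    """Probes x samples matrix of bulk methylation beta values (the D matrix)."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (M, N)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (probes x samples)")
        m, n = self.values.shape
        if len(self.probe_ids) != m or len(self.sample_ids) != n:
            raise ValueError("id lists inconsistent with value matrix shape")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("beta values must be finite")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(
            probe_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, path) -> "BetaMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        index = {p: i for i, p in enumerate(self.probe_ids)}
        rows = [index[p] for p in probe_ids]
        return BetaMatrix(list(probe_ids), list(self.sample_ids), self.values[rows])


@dataclass
class IndividualProfiles:
    """Per-individual perturbed cell-type profiles: an (N, M, K) stack."""

    probe_ids: list[str]
    type_names: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (N, M, K)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m, k = self.values.shape
        if (len(self.sample_ids), len(self.probe_ids), len(self.type_names)) != (n, m, k):
            raise ValueError("id lists inconsistent with value stack shape")

    def probe_positions(self, probe_ids) -> np.ndarray:
        index = {p: i for i, p in enumerate(self.probe_ids)}
        try:
            return np.array([index[p] for p in probe_ids], dtype=int)
        except KeyError as exc:
            raise ValueError(f"unknown probe id {exc.args[0]!r} in effects") from None


@dataclass
class SimulationTruth:
    """Everything needed to score a deconvolution of the simulated cohort."""

    A_true: ProportionMatrix
    T_base: CellTypeProfiles
    individual_profiles: IndividualProfiles
    effects: ConfounderEffects | None
    config: SimulationConfig


def simulate_proportions(config: SimulationConfig) -> ProportionMatrix:
    """Draw the A matrix: each sample's proportions ~ Dirichlet(alpha0 * base_props)."""
    rng = np.random.default_rng(config.seed)
    alpha = config.alpha0 * np.asarray(config.base_props)
    values = rng.dirichlet(alpha, size=config.n_samples).T  # (K, N)
    # guard against exact zeros from extreme draws so columns stay on the simplex
    values = np.clip(values, 0.0, 1.0)
    values /= values.sum(axis=0, keepdims=True)
    names = list(
        DEFAULT_TYPE_NAMES.get(
            config.n_types, tuple(f"type_{i + 1}" for i in range(config.n_types))
        )
    )
    sample_ids = [f"sample{i:04d}" for i in range(config.n_samples)]
    return ProportionMatrix(names, sample_ids, values)


def tile_profiles(base: CellTypeProfiles, sample_ids) -> IndividualProfiles:
    """Replicate the base T matrix into one copy per individual."""
    n = len(sample_ids)
    stack = np.broadcast_to(base.values, (n,) + base.values.shape).copy()
    return IndividualProfiles(
        list(base.probe_ids), list(base.type_names), list(sample_ids), stack
    )


def _check_samples(profiles: IndividualProfiles, metadata: CohortMetadata) -> None:
    if list(profiles.sample_ids) != list(metadata.sample_ids):
        raise ValueError("sample ids of profiles and metadata do not match")


def apply_sex_effect(
    profiles: IndividualProfiles,
    metadata: CohortMetadata,
    effects: ConfounderEffects,
) -> IndividualProfiles:
    """Shift sex-probe values (all cell-type columns alike) for the shifted sex group."""
    _check_samples(profiles, metadata)
    idx = profiles.probe_positions(effects.sex_probe_ids)
    out = profiles.values.copy()
    shifted = np.asarray(metadata["sex"]) == effects.shifted_sex
    if idx.size and shifted.any():
        block = out[np.ix_(np.flatnonzero(shifted), idx)]
        out[np.ix_(np.flatnonzero(shifted), idx)] = np.clip(
            block + effects.sex_coefs[None, :, None], 0.0, 1.0
        )
    return IndividualProfiles(
        profiles.probe_ids, profiles.type_names, profiles.sample_ids, out
    )


def apply_age_effect(
    profiles: IndividualProfiles,
    metadata: CohortMetadata,
    effects: ConfounderEffects,
) -> IndividualProfiles:
    """Overwrite age-probe values with the individual's linear-in-age prediction.

    The epithelial column receives ``intercept + slope * age``; every other
    type receives that prediction times its per-probe ratio coefficient.
    Results are clamped to [0, 1].
    """
    _check_samples(profiles, metadata)
    if list(profiles.type_names) != list(effects.type_names):
        raise ValueError("type names of profiles and effects do not match")
    idx = profiles.probe_positions(effects.age_probe_ids)
    out = profiles.values.copy()
    if idx.size:
        ages = np.asarray(metadata["age"], dtype=float)  # (N,)
        pred = effects.age_intercepts[None, :] + effects.age_slopes[None, :] * ages[:, None]
        out[:, idx, :] = np.clip(pred[:, :, None] * effects.type_ratios[None, :, :], 0.0, 1.0)
    return IndividualProfiles(
        profiles.probe_ids, profiles.type_names, profiles.sample_ids, out
    )


def mix(truth: SimulationTruth) -> BetaMatrix:
    """Form the bulk matrix: column i of D = (individual i's T) @ (column i of A)."""
    profiles = truth.individual_profiles
    a = truth.A_true
    if list(profiles.sample_ids) != list(a.sample_ids):
        raise ValueError("sample ids of profiles and proportions do not match")
    if profiles.values.shape[2] != a.n_types:
        raise ValueError("number of cell types of profiles and proportions do not match")
    d = np.einsum("nmk,kn->mn", profiles.values, a.values)
    d = np.clip(d, 0.0, 1.0)  # convex combination; clip guards rounding only
    return BetaMatrix(list(profiles.probe_ids), list(profiles.sample_ids), d)


def apply_plate_effect(
    D: BetaMatrix, metadata: CohortMetadata, effects: ConfounderEffects
) -> BetaMatrix:
    """Multiply each sample's column by its plate coefficient, clamped to [0, 1]."""
    if list(D.sample_ids) != list(metadata.sample_ids):
        raise ValueError("sample ids of matrix and metadata do not match")
    coef_map = effects.plate_coef_map
    plates = list(metadata["plate"])
    unknown = sorted({p for p in plates if p not in coef_map})
    if unknown:
        raise ValueError(f"no plate coefficient for label(s) {unknown}")
    coefs = np.array([coef_map[p] for p in plates])
    values = np.clip(D.values * coefs[None, :], 0.0, 1.0)
    return BetaMatrix(list(D.probe_ids), list(D.sample_ids), values)


def add_noise(D: BetaMatrix, epsilon: float, seed: int = 0) -> BetaMatrix:
    """Add entry-wise Gaussian(0, epsilon) noise with the skip-at-boundary rule.

    If the noisy value would leave [0, 1] the draw is discarded and the
    original value kept (no clamping).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0:
        return BetaMatrix(list(D.probe_ids), list(D.sample_ids), D.values.copy())
    rng = np.random.default_rng(seed)
    candidate = D.values + rng.normal(0.0, epsilon, D.values.shape)
    keep = (candidate >= 0.0) & (candidate <= 1.0)
    values = np.where(keep, candidate, D.values)
    return BetaMatrix(list(D.probe_ids), list(D.sample_ids), values)


def simulate_dataset(
    config: SimulationConfig,
    profiles: CellTypeProfiles,
    metadata: CohortMetadata | None = None,
    effects: ConfounderEffects | None = None,
) -> tuple[BetaMatrix, SimulationTruth]:
    """Run the full simulation: A, per-individual T perturbation, mix, plate, noise.

    ``metadata``/``effects`` may be omitted, in which case no confounder
    stage is applied.  All stage seeds derive deterministically from
    ``config.seed``.
    """
    if profiles.n_types != config.n_types:
        raise ValueError("profiles and config disagree on the number of cell types")
    a = simulate_proportions(config)
    if metadata is not None and metadata.n_samples != config.n_samples:
        raise ValueError("metadata and config disagree on the number of samples")
    sample_ids = metadata.sample_ids if metadata is not None else a.sample_ids
    a = ProportionMatrix(a.type_names, list(sample_ids), a.values)

    stack = tile_profiles(profiles, sample_ids)
    if effects is not None:
        if metadata is None:
            raise ValueError("effects require cohort metadata")
        stack = apply_sex_effect(stack, metadata, effects)
        stack = apply_age_effect(stack, metadata, effects)

    truth = SimulationTruth(
        A_true=a,
        T_base=profiles,
        individual_profiles=stack,
        effects=effects,
        config=config,
    )
    d = mix(truth)
    noise_seed = (config.seed * 7919 + 1) % (2**31)
    if effects is not None and metadata is not None:
        if config.plate_before_noise:
            d = apply_plate_effect(d, metadata, effects)
            d = add_noise(d, config.epsilon, noise_seed)
        else:
            d = add_noise(d, config.epsilon, noise_seed)
            d = apply_plate_effect(d, metadata, effects)
    else:
        d = add_noise(d, config.epsilon, noise_seed)
    return d, truth
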