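"""Synthetic reference profiles, cohort metadata and confounder-effect parameters.

Real reference-free deconvolution studies start from purified cell-type
methylomes (Illumina 27K/450K beta values) and clinical covariate tables.
This module generates stand-ins with the salient statistical features of
such data:

* beta values are bimodal -- most CpG probes sit near 0 (unmethylated) or
  near 1 (fully methylated);
* a minority of probes ("informative loci") differ between cell types, the
  rest share a common baseline across types;
* a subset of probes carries sex-, age- or plate- (batch-) associated
  effects, the classic measured confounders of methylation studies.

All generators are deterministic functions of an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CellTypeProfiles",
    "CohortMetadata",
    "ConfounderEffects",
    "make_reference_profiles",
    "make_cohort",
    "make_confounder_effects",
    "DEFAULT_TYPE_NAMES",
]

# canonical cell backgrounds for the lung-tumour mixture model
DEFAULT_TYPE_NAMES = {
    5: (
        "fibroblast",
        "cancer_epithelial",
        "t_lymphocyte",
        "control_epithelial",
        "cancer_mesenchymal",
    ),
    3: ("fibroblast", "cancer_epithelial", "t_lymphocyte"),
}

#: number of sex-associated probes carried by the default confounder model
DEFAULT_N_SEX_PROBES = 1397
#: number of age-associated probes carried by the default confounder model
DEFAULT_N_AGE_PROBES = 113
#: number of processing plates (batches) in the default confounder model
DEFAULT_N_PLATES = 22


@dataclass
class CellTypeProfiles:
    """Probes x cell-types matrix of type-specific beta profiles (the T matrix)."""

    probe_ids: list[str]
    type_names: list[str]
    values: np.ndarray  # (M, K), beta values in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (probes x types) array")
        m, k = self.values.shape
        if len(self.probe_ids) != m or len(self.type_names) != k:
            raise ValueError("id lists inconsistent with value matrix shape")
        if len(set(self.probe_ids)) != m:
            raise ValueError("probe_ids must be unique")
        if len(set(self.type_names)) != k:
            raise ValueError("type_names must be unique")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("profile values must be finite")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("profile values must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_types(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.type_names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CellTypeProfiles":
        return cls(
            probe_ids=[str(i) for i in frame.index],
            type_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, path) -> "CellTypeProfiles":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))

    def subset_probes(self, probe_ids) -> "CellTypeProfiles":
        index = {p: i for i, p in enumerate(self.probe_ids)}
        rows = [index[p] for p in probe_ids]
        return CellTypeProfiles(list(probe_ids), list(self.type_names), self.values[rows])


@dataclass
class CohortMetadata:
    """Per-sample covariate table: sex, age, plate and arbitrary extras."""

    table: pd.DataFrame  # indexed by sample id

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("sample_ids must be unique")
        if "age" in self.table.columns and (self.table["age"] < 0).any():
            raise ValueError("age must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.table.index]

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def __getitem__(self, column: str) -> pd.Series:
        return self.table[column]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "CohortMetadata":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class ConfounderEffects:
    """Parameters of the sex / age / plate perturbation model.

    sex: an additive per-probe shift applied (in every cell-type column) to
    individuals of the shifted sex group.  age: a per-probe linear-in-age
    prediction assigned to the designated epithelial type, propagated to the
    other types through per-probe ratio coefficients.  plate: a per-batch
    multiplicative factor on all probes.
    """

    sex_probe_ids: list[str]
    sex_coefs: np.ndarray  # (n_sex,)
    age_probe_ids: list[str]
    age_slopes: np.ndarray  # (n_age,) beta change per year
    age_intercepts: np.ndarray  # (n_age,)
    type_ratios: np.ndarray  # (n_age, K) ratio of each type to the epithelial type
    type_names: list[str]
    epithelial_type: str
    plate_labels: list[str]
    plate_coefs: np.ndarray  # (n_plates,), reference plate fixed at 1
    shifted_sex: int = 1  # group receiving the additive sex shift

    def __post_init__(self) -> None:
        self.sex_coefs = np.asarray(self.sex_coefs, dtype=float)
        self.age_slopes = np.asarray(self.age_slopes, dtype=float)
        self.age_intercepts = np.asarray(self.age_intercepts, dtype=float)
        self.type_ratios = np.asarray(self.type_ratios, dtype=float)
        self.plate_coefs = np.asarray(self.plate_coefs, dtype=float)
        if len(self.sex_probe_ids) != self.sex_coefs.shape[0]:
            raise ValueError("sex coefficient list does not align with its probe ids")
        n_age = len(self.age_probe_ids)
        if self.age_slopes.shape[0] != n_age or self.age_intercepts.shape[0] != n_age:
            raise ValueError("age coefficient lists do not align with their probe ids")
        if self.type_ratios.shape != (n_age, len(self.type_names)):
            raise ValueError("type_ratios must be (n_age_probes, n_types)")
        if self.epithelial_type not in self.type_names:
            raise ValueError(f"unknown epithelial type {self.epithelial_type!r}")
        if len(self.plate_labels) != self.plate_coefs.shape[0]:
            raise ValueError("plate coefficient list does not align with its labels")
        if self.plate_coefs.shape[0] and abs(self.plate_coefs[0] - 1.0) > 1e-12:
            raise ValueError("reference (first) plate coefficient must equal 1")

    @property
    def plate_coef_map(self) -> dict[str, float]:
        return dict(zip(self.plate_labels, self.plate_coefs.tolist()))

    def to_yaml(self, path) -> None:
        payload = {
            "sex_probe_ids": list(self.sex_probe_ids),
            "sex_coefs": self.sex_coefs.tolist(),
            "age_probe_ids": list(self.age_probe_ids),
            "age_slopes": self.age_slopes.tolist(),
            "age_intercepts": self.age_intercepts.tolist(),
            "type_ratios": self.type_ratios.tolist(),
            "type_names": list(self.type_names),
            "epithelial_type": self.epithelial_type,
            "plate_labels": list(self.plate_labels),
            "plate_coefs": self.plate_coefs.tolist(),
            "shifted_sex": int(self.shifted_sex),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "ConfounderEffects":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


def _bimodal_betas(rng: np.random.Generator, size, weight_high: float = 0.5) -> np.ndarray:
    """Draw beta values from the canonical bimodal array distribution.

    A 50/50 mixture of Beta(2, 20) (unmethylated mode, mean ~0.09) and
    Beta(20, 2) (methylated mode, mean ~0.91).
    """
    high = rng.random(size) < weight_high
    low_draw = rng.beta(2.0, 20.0, size)
    high_draw = rng.beta(20.0, 2.0, size)
    return np.where(high, high_draw, low_draw)


def make_reference_profiles(
    n_probes: int,
    n_types: int,
    frac_informative: float = 0.2,
    divergence: float = 0.8,
    seed: int = 0,
    type_names: list[str] | None = None,
) -> CellTypeProfiles:
    """Generate synthetic purified cell-type methylomes.

    A fraction ``frac_informative`` of probes carries cell-type-specific
    methylation: their per-type values interpolate between a shared bimodal
    baseline (``divergence=0``, all types identical) and fully independent
    bimodal draws per type (``divergence=1``).  The remaining probes are
    identical across types.

    Parameters
    ----------
    n_probes, n_types
        Matrix dimensions; ``n_probes >= n_types >= 2``.
    frac_informative
        Share of probes that differ between types, in (0, 1].
    divergence
        Interpolation weight in [0, 1] between the shared baseline and
        independent per-type draws at informative probes.  Controls how
        separable the cell types are.
    seed
        Seed of the single generator driving all randomness.
    """
    if n_types < 2 or n_probes < n_types:
        raise ValueError("require n_probes >= n_types >= 2")
    if not 0 < frac_informative <= 1:
        raise ValueError("frac_informative must be in (0, 1]")
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")

    rng = np.random.default_rng(seed)
    baseline = _bimodal_betas(rng, n_probes)
    n_inf = int(round(frac_informative * n_probes))
    informative = rng.choice(n_probes, size=n_inf, replace=False)
    per_type = _bimodal_betas(rng, (n_inf, n_types))

    values = np.repeat(baseline[:, None], n_types, axis=1)
    values[informative] = (1.0 - divergence) * baseline[informative, None] + divergence * per_type

    if type_names is None:
        type_names = list(
            DEFAULT_TYPE_NAMES.get(n_types, tuple(f"type_{i + 1}" for i in range(n_types)))
        )
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    return CellTypeProfiles(probe_ids, list(type_names), values)


def make_cohort(
    n_samples: int,
    n_plates: int = DEFAULT_N_PLATES,
    seed: int = 0,
    age_range: tuple[float, float] = (40.0, 80.0),
    plate_assignment: str = "round_robin",
) -> CohortMetadata:
    """Generate a cohort metadata table (sex, age, plate).

    Sex is an exactly balanced binary indicator in random order, age is
    uniform over ``age_range`` (years), plates are assigned round-robin
    (default) or at random.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not 1 <= n_plates <= n_samples:
        raise ValueError("require 1 <= n_plates <= n_samples")

    rng = np.random.default_rng(seed)
    sex = np.zeros(n_samples, dtype=int)
    sex[: n_samples // 2] = 1
    sex = rng.permutation(sex)
    age = rng.uniform(age_range[0], age_range[1], n_samples)
    if plate_assignment == "round_robin":
        plate_idx = np.arange(n_samples) % n_plates
    elif plate_assignment == "random":
        plate_idx = rng.integers(0, n_plates, n_samples)
    else:
        raise ValueError(f"unknown plate_assignment {plate_assignment!r}")
    plates = [f"plate{p:02d}" for p in plate_idx]

    table = pd.DataFrame(
        {"sex": sex, "age": age, "plate": plates},
        index=pd.Index([f"sample{i:04d}" for i in range(n_samples)], name="sample_id"),
    )
    return CohortMetadata(table)


def make_confounder_effects(
    profiles: CellTypeProfiles,
    n_sex_probes: int = DEFAULT_N_SEX_PROBES,
    n_age_probes: int = DEFAULT_N_AGE_PROBES,
    n_plates: int = DEFAULT_N_PLATES,
    effect_scale: float = 0.2,
    seed: int = 0,
    epithelial_type: str | None = None,
    age_reference: float = 60.0,
) -> ConfounderEffects:
    """Draw sex / age / plate effect parameters for a profile set.

    Sex shifts have magnitude ``effect_scale * U(0.5, 1.5)`` with random
    sign (bounded away from 0, emulating probes pre-selected for a
    significant sex association).  Age slopes are
    ``+/- effect_scale * U(0.01, 0.02)`` beta units per year; intercepts are
    anchored so the epithelial prediction equals the base profile at
    ``age_reference`` years.  Per-probe per-type ratio coefficients are the
    ratio of each type's base value to the epithelial type's, so at
    ``effect_scale = 0`` the whole perturbation is the identity.  Plate
    multipliers are ``1 + effect_scale * U(-0.1, 0.1)`` with the first
    (reference) plate fixed at exactly 1.
    """
    m = profiles.n_probes
    if n_sex_probes < 0 or n_age_probes < 0 or n_plates < 1:
        raise ValueError("invalid counts")
    if n_sex_probes + n_age_probes > m:
        raise ValueError(
            f"cannot pick {n_sex_probes} sex + {n_age_probes} age disjoint probes "
            f"from a universe of {m}"
        )
    if epithelial_type is None:
        for candidate in ("control_epithelial", "cancer_epithelial"):
            if candidate in profiles.type_names:
                epithelial_type = candidate
                break
        else:
            epithelial_type = profiles.type_names[0]

    rng = np.random.default_rng(seed)
    chosen = rng.choice(m, size=n_sex_probes + n_age_probes, replace=False)
    sex_idx, age_idx = chosen[:n_sex_probes], chosen[n_sex_probes:]
    probe_arr = np.asarray(profiles.probe_ids, dtype=object)

    sex_coefs = (
        effect_scale
        * rng.uniform(0.5, 1.5, n_sex_probes)
        * rng.choice([-1.0, 1.0], n_sex_probes)
    )
    age_slopes = (
        effect_scale
        * rng.uniform(0.01, 0.02, n_age_probes)
        * rng.choice([-1.0, 1.0], n_age_probes)
    )
    epi_col = profiles.type_names.index(epithelial_type)
    epi_base = profiles.values[age_idx, epi_col]
    age_intercepts = epi_base - age_slopes * age_reference

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = profiles.values[age_idx] / epi_base[:, None]
    ratios[~np.isfinite(ratios)] = 1.0

    plate_coefs = 1.0 + effect_scale * rng.uniform(-0.1, 0.1, n_plates)
    plate_coefs[0] = 1.0
    plate_labels = [f"plate{p:02d}" for p in range(n_plates)]

    return ConfounderEffects(
        sex_probe_ids=list(probe_arr[sex_idx]),
        sex_coefs=sex_coefs,
        age_probe_ids=list(probe_arr[age_idx]),
        age_slopes=age_slopes,
        age_intercepts=age_intercepts,
        type_ratios=ratios,
        type_names=list(profiles.type_names),
        epithelial_type=epithelial_type,
        plate_labels=plate_labels,
        plate_coefs=plate_coefs,
    )
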