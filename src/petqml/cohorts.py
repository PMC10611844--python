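"""Synthetic radiomic cohort generation.

Real PET radiomic cohorts used in this line of work (prostate PSMA-11 lesion
tables, MET glioma, FDG lung) are not publicly deposited, so the pipeline is
exercised on synthetic cohorts that reproduce the statistical structure the
downstream analysis assumes:

* lesion-level rows carrying a patient identifier, with a patient-level
  binary endpoint shared by all lesions of one patient;
* blocks of mutually redundant features, built as monotone transforms of a
  shared latent variable so the within-block Spearman correlation is
  directly controllable;
* a set of informative features whose class means differ by a prescribed
  standardized effect size; and
* remaining columns of pure noise with heterogeneous scales.

Spearman correlation is invariant under monotone maps, which is what makes
``rho_target`` controllable: block members are noisy copies of one latent
parent with the latent Pearson correlation chosen via the Gaussian
rank-correlation identity rho_s = (6/pi) * arcsin(r/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["CohortSpec", "FeatureTable", "generate_cohort", "make_three_cohort_suite"]

#: lesion-count distribution used by default: most patients contribute a
#: single lesion, a minority contribute two or three.
DEFAULT_LESION_DIST: Mapping[int, float] = {1: 0.80, 2: 0.12, 3: 0.08}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Parameters
    ----------
    n_patients
        Number of patients; each contributes one or more lesion rows.
    lesions_per_patient
        Distribution over small positive lesion counts, as ``{count: prob}``.
    n_features
        Total feature columns.
    n_informative
        Features whose class means are separated by ``delta`` standard
        deviations.
    n_blocks, block_size
        Number and width of redundant feature blocks.
    rho_target
        Target within-block Spearman |rho| in [0, 1].
    delta
        Standardized class-mean difference of informative features (>= 0).
    prevalence
        Positive-class fraction of patients, in (0, 1).
    seed
        Seed for all randomness of the generator.
    n_samples
        Optional exact number of lesion rows; when set, patients are drawn
        until the target is met and the last patient is trimmed.
    """

    n_patients: int
    n_features: int = 100
    n_informative: int = 10
    n_blocks: int = 10
    block_size: int = 5
    rho_target: float = 0.8
    delta: float = 1.0
    prevalence: float = 0.5
    seed: int = 0
    lesions_per_patient: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LESION_DIST)
    )
    n_samples: int | None = None

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ConfigurationError("n_patients must be >= 4")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if self.n_informative > self.n_features:
            raise ConfigurationError("n_informative exceeds n_features")
        if self.n_blocks * self.block_size > self.n_features:
            raise ConfigurationError("n_blocks * block_size exceeds n_features")
        if self.n_informative + self.n_blocks * self.block_size > self.n_features:
            raise ConfigurationError(
                "n_informative + n_blocks * block_size exceeds n_features "
                "(informative, block and noise columns are disjoint)"
            )
        if not 0.0 <= self.rho_target <= 1.0:
            raise ConfigurationError("rho_target must be in [0, 1]")
        if self.delta < 0:
            raise ConfigurationError("delta must be >= 0")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must be in (0, 1)")
        probs = np.array(list(self.lesions_per_patient.values()), dtype=float)
        counts = np.array(list(self.lesions_per_patient.keys()), dtype=int)
        if (counts < 1).any() or probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ConfigurationError("lesions_per_patient must be a distribution over positive counts")


class FeatureTable:
    """Lesion-level feature table: the tabular currency of the pipeline.

    Wraps a :class:`pandas.DataFrame` with mandatory columns
    ``sample_id, patient_id, label`` followed by numeric feature columns.
    """

    META_COLS = ("sample_id", "patient_id", "label")

    def __init__(self, df: pd.DataFrame):
        for col in self.META_COLS:
            if col not in df.columns:
                raise ConfigurationError(f"FeatureTable missing column {col!r}")
        if df["sample_id"].duplicated().any():
            raise ConfigurationError("duplicate sample_id values")
        if not set(df["label"].unique()) <= {0, 1}:
            raise ConfigurationError("labels must be binary 0/1")
        feats = df.drop(columns=list(self.META_COLS))
        if not np.isfinite(feats.to_numpy(dtype=float)).all():
            raise ConfigurationError("non-finite feature values")
        per_patient = df.groupby("patient_id")["label"].nunique()
        if (per_patient > 1).any():
            bad = per_patient[per_patient > 1].index[0]
            raise ConfigurationError(f"patient {bad!r} has inconsistent labels")
        self.df = df.reset_index(drop=True)

    # -- accessors -------------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in self.META_COLS]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.df["sample_id"].to_numpy()

    @property
    def patient_ids(self) -> np.ndarray:
        return self.df["patient_id"].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=int)

    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_names].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, sample_ids: Sequence[str]) -> "FeatureTable":
        """Rows for the given sample ids, in table order."""
        wanted = set(sample_ids)
        return FeatureTable(self.df[self.df["sample_id"].isin(wanted)].copy())

    def select_features(self, names: Sequence[str]) -> "FeatureTable":
        cols = list(self.META_COLS) + list(names)
        return FeatureTable(self.df[cols].copy())

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path))


def _latent_pearson_for_spearman(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian with Spearman rho_s."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


# monotone maps applied to block members; Spearman-invariant by construction
_MONOTONE_MAPS = (
    lambda z: z,
    lambda z: z**3,
    lambda z: np.expm1(0.5 * z),
    lambda z: np.sign(z) * np.abs(z) ** 1.5,
    lambda z: np.arctan(z),
)


def generate_cohort(spec: CohortSpec) -> FeatureTable:
    """Generate one synthetic cohort according to ``spec``.

    Deterministic given ``spec.seed``. Labels are drawn per patient (all
    lesions of one patient share the endpoint); the number of positive
    patients is fixed at ``round(prevalence * n_patients)`` so class balance
    does not fluctuate across seeds.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # patient structure
    counts = np.array(list(spec.lesions_per_patient.keys()), dtype=int)
    probs = np.array(list(spec.lesions_per_patient.values()), dtype=float)
    lesion_counts = rng.choice(counts, size=spec.n_patients, p=probs)
    if spec.n_samples is not None:
        # draw additional patients (or trim) until the exact row count is hit
        lesion_counts = list(lesion_counts)
        total = int(np.sum(lesion_counts))
        while total < spec.n_samples:
            c = int(rng.choice(counts, p=probs))
            lesion_counts.append(c)
            total += c
        while total > spec.n_samples:
            if lesion_counts[-1] > 1:
                lesion_counts[-1] -= 1
            else:
                lesion_counts.pop()
            total -= 1
        lesion_counts = np.array(lesion_counts, dtype=int)
    n_patients = len(lesion_counts)

    n_pos = int(round(spec.prevalence * n_patients))
    n_pos = min(max(n_pos, 2), n_patients - 2)  # both classes always present
    patient_labels = np.zeros(n_patients, dtype=int)
    patient_labels[rng.permutation(n_patients)[:n_pos]] = 1

    patient_ids = np.repeat([f"P{i:04d}" for i in range(n_patients)], lesion_counts)
    labels = np.repeat(patient_labels, lesion_counts)
    n = len(labels)
    sample_ids = [f"S{i:04d}" for i in range(n)]

    X = np.empty((n, spec.n_features))
    col = 0

    # informative columns: class means separated by delta within-class SDs;
    # the shift direction varies per feature, as it does in real radiomics
    # (a uniform shift would be near-invisible to amplitude encoding, which
    # normalizes away the component parallel to the mean vector)
    for _ in range(spec.n_informative):
        sign = rng.choice((-1.0, 1.0))
        X[:, col] = sign * spec.delta * labels + rng.standard_normal(n)
        col += 1

    # redundant blocks: noisy monotone copies of one latent parent
    if spec.rho_target >= 1.0:
        noise_sd = 0.0
    elif spec.rho_target <= 0.0:
        noise_sd = np.inf
    else:
        r = _latent_pearson_for_spearman(spec.rho_target)
        noise_sd = np.sqrt(1.0 / r - 1.0)
    for _ in range(spec.n_blocks):
        parent = rng.standard_normal(n)
        for j in range(spec.block_size):
            if np.isinf(noise_sd):
                member = rng.standard_normal(n)
            else:
                member = parent + noise_sd * rng.standard_normal(n)
            X[:, col] = _MONOTONE_MAPS[j % len(_MONOTONE_MAPS)](member)
            col += 1

    # remaining columns: independent noise
    while col < spec.n_features:
        X[:, col] = rng.standard_normal(n)
        col += 1

    # heterogeneous scales/offsets, mimicking raw radiomic magnitudes;
    # affine maps are monotone, so Spearman structure is untouched
    scales = 10.0 ** rng.uniform(-1, 2, size=spec.n_features)
    offsets = rng.uniform(-5, 5, size=spec.n_features)
    X = X * scales + offsets

    data = {
        "sample_id": sample_ids,
        "patient_id": patient_ids,
        "label": labels,
    }
    width = len(str(spec.n_features))
    for j in range(spec.n_features):
        data[f"f_{j + 1:0{max(width, 4)}d}"] = X[:, j]
    return FeatureTable(pd.DataFrame(data))


def block_columns(spec: CohortSpec) -> list[list[str]]:
    """Feature names of each redundant block, per the generator's layout."""
    width = max(len(str(spec.n_features)), 4)
    names = [f"f_{j + 1:0{width}d}" for j in range(spec.n_features)]
    out = []
    start = spec.n_informative
    for b in range(spec.n_blocks):
        out.append(names[start + b * spec.block_size : start + (b + 1) * spec.block_size])
    return out


def three_cohort_specs(seed: int) -> list[CohortSpec]:
    """Cohort specs emulating the three study datasets.

    The prostate-like cohort has 121 lesion rows with multi-lesion patients;
    the glioma-like (84) and lung-like (335) cohorts are one lesion per case.
    """
    return [
        CohortSpec(
            n_patients=95,
            n_samples=121,
            delta=0.6,
            prevalence=0.5,
            seed=seed,
        ),
        CohortSpec(
            n_patients=84,
            n_samples=84,
            lesions_per_patient={1: 1.0},
            delta=0.6,
            prevalence=0.45,
            seed=seed + 1_000_003,
        ),
        CohortSpec(
            n_patients=335,
            n_samples=335,
            lesions_per_patient={1: 1.0},
            delta=0.6,
            prevalence=0.35,
            seed=seed + 2_000_003,
        ),
    ]


def make_three_cohort_suite(seed: int) -> list[FeatureTable]:
    """Three synthetic cohorts with 121, 84, and 335 lesion rows.

    Shapes follow the prostate / glioma / lung study datasets; the feature
    content is synthetic (see :func:`generate_cohort`).
    """
    return [generate_cohort(s) for s in three_cohort_specs(seed)]
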