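"""Patient-grouped, test-balanced Monte-Carlo cross-validation.

The study design is ten repeated random 80:20 train/test resamples per
cohort ("tenfold" with an 80:20 ratio cannot be a disjoint partition, since
10 x 20% > 100%; repeated resampling is the only consistent reading). The
splits obey three hard constraints:

* **patient grouping** — all lesions of a patient land on the same side of
  the split, so no patient-level information leaks from train to test;
* **exact test balance** — every test set has exactly as many positive as
  negative lesions, achieved by moving excess majority-class patients back
  to train (residual excess lesions of a multi-lesion patient are excluded
  from the fold entirely, preserving patient disjointness);
* **harmonization** — the same fold assignments are reused across every
  SRT x feature-count variant of a cohort, so method comparisons are not
  confounded by split noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .cohorts import FeatureTable
from .errors import ConfigurationError, SizingError

__all__ = ["FoldSplit", "CVScheme", "make_cv_scheme", "harmonize"]

N_FOLDS = 10
TEST_FRACTION = 0.2


@dataclass(frozen=True)
class FoldSplit:
    """One train/test split, by sample id."""

    fold_id: int
    train_ids: frozenset[str]
    test_ids: frozenset[str]

    def __post_init__(self):
        if self.train_ids & self.test_ids:
            raise ConfigurationError("train and test overlap")


@dataclass(frozen=True)
class CVScheme:
    """Ten seeded folds for one cohort."""

    cohort_id: str
    seed: int
    folds: tuple[FoldSplit, ...]

    def fold_hash(self) -> str:
        """Stable digest of the fold assignments (harmonization checks)."""
        payload = json.dumps(
            [[sorted(f.train_ids), sorted(f.test_ids)] for f in self.folds]
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(
            {
                "cohort_id": self.cohort_id,
                "seed": self.seed,
                "folds": [
                    {
                        "fold_id": f.fold_id,
                        "train_ids": sorted(f.train_ids),
                        "test_ids": sorted(f.test_ids),
                    }
                    for f in self.folds
                ],
            },
            indent=1,
        )


def _one_split(
    sample_ids: np.ndarray,
    patient_ids: np.ndarray,
    labels: np.ndarray,
    fold_id: int,
    rng: np.random.Generator,
) -> FoldSplit:
    patients: dict[str, dict] = {}
    for sid, pid, y in zip(sample_ids, patient_ids, labels):
        patients.setdefault(pid, {"label": int(y), "samples": []})["samples"].append(sid)

    n_total = len(sample_ids)
    target_test = TEST_FRACTION * n_total

    test_patients: list[str] = []
    # stratified draw: fill each class's share of the test set by whole patients
    for cls in (1, 0):
        cls_pats = [p for p, d in patients.items() if d["label"] == cls]
        rng.shuffle(cls_pats)
        cls_n = sum(len(patients[p]["samples"]) for p in cls_pats)
        cls_target = target_test * cls_n / n_total
        got = 0
        for p in cls_pats:
            if got >= cls_target:
                break
            test_patients.append(p)
            got += len(patients[p]["samples"])

    test_set = set(test_patients)
    test_samples = {
        cls: [s for p in test_set if patients[p]["label"] == cls for s in patients[p]["samples"]]
        for cls in (0, 1)
    }
    n_pos, n_neg = len(test_samples[1]), len(test_samples[0])
    if min(n_pos, n_neg) == 0:
        raise SizingError("cohort too small to balance a test set")

    # balance: move whole majority-class patients back to train; drop any
    # residual excess lesions of a multi-lesion patient from the fold
    excluded: set[str] = set()
    maj = 1 if n_pos > n_neg else 0
    excess = abs(n_pos - n_neg)
    if excess:
        maj_patients = sorted(
            (p for p in test_set if patients[p]["label"] == maj),
            key=lambda p: -len(patients[p]["samples"]),
        )
        for p in maj_patients:
            k = len(patients[p]["samples"])
            if excess == 0:
                break
            if k <= excess:
                test_set.remove(p)  # whole patient returns to train
                excess -= k
            elif len(maj_patients) == 1 or p == maj_patients[-1]:
                drop = rng.choice(patients[p]["samples"], size=excess, replace=False)
                excluded.update(drop.tolist())
                excess = 0
        if excess:  # only single-lesion patients left yet excess remains
            raise SizingError("cannot balance test set")

    test_ids = frozenset(
        s
        for p in test_set
        for s in patients[p]["samples"]
        if s not in excluded
    )
    train_ids = frozenset(
        s for p in patients if p not in test_set for s in patients[p]["samples"]
    )
    return FoldSplit(fold_id=fold_id, train_ids=train_ids, test_ids=test_ids)


def make_cv_scheme(table: FeatureTable, seed: int, cohort_id: str = "cohort") -> CVScheme:
    """Build the ten seeded patient-grouped balanced splits for one cohort."""
    labels = table.labels
    pids = table.patient_ids
    for cls in (0, 1):
        if len(set(pids[labels == cls])) < 2:
            raise ConfigurationError(f"need >= 2 patients of class {cls}")
    rng = np.random.default_rng(seed)
    folds = tuple(
        _one_split(table.sample_ids, pids, labels, fold_id, rng)
        for fold_id in range(1, N_FOLDS + 1)
    )
    return CVScheme(cohort_id=cohort_id, seed=seed, folds=folds)


def harmonize(
    scheme: CVScheme, variant_tables: list[FeatureTable]
) -> list[tuple[FeatureTable, CVScheme]]:
    """Attach the identical fold splits to every variant of the cohort.

    Every variant must be row-aligned (same sample ids) with the cohort the
    scheme was built on.
    """
    ref_ids = set().union(*(f.train_ids | f.test_ids for f in scheme.folds))
    out = []
    for t in variant_tables:
        ids = set(t.sample_ids)
        if not ref_ids <= ids:
            missing = sorted(ref_ids - ids)[:5]
            raise ConfigurationError(f"variant missing sample ids (e.g. {missing})")
        out.append((t, scheme))
    return out
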