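"""Feature-table preparation for quantum encoding.

Three stages, mirroring the standard radiomics-to-qubits workflow:

1. **Redundancy reduction** — features whose pairwise |Spearman rho| reaches
   a threshold (SRT) are clustered as connected components of the
   thresholded correlation graph; the highest-variance member of each
   cluster survives. Applied once per cohort per SRT, before any
   cross-validation.
2. **R-squared ranking** — within each fold, features are scored on the
   *training* rows by the R-squared of the univariate linear fit of the
   binary endpoint on the feature (the squared Pearson correlation between
   feature and label) and the top 8 or 16 are kept.
3. **Scaling and zero-padding** — selected features are standardized with
   train-set statistics, mapped to [0, 1], zero-padded to the next power of
   two and L2-normalized so they can be amplitude-encoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .cohorts import FeatureTable
from .errors import ConfigurationError, EncodingError

__all__ = [
    "PrepConfig",
    "RedundancyReport",
    "spearman_redundancy_reduce",
    "r2_rank_select",
    "FeatureScaler",
    "zero_pad_normalize",
]


@dataclass(frozen=True)
class PrepConfig:
    """Preparation parameters: Spearman rank threshold and feature count."""

    srt: float = 0.7
    n_select: int = 8

    def __post_init__(self):
        if not 0.0 < self.srt <= 1.0:
            raise ConfigurationError("srt must be in (0, 1]")
        n = self.n_select
        if n < 2 or (n & (n - 1)) != 0:
            raise ConfigurationError("n_select must be a power of two > 1")


@dataclass
class RedundancyReport:
    """Outcome of one redundancy-reduction pass."""

    clusters: list[list[str]]
    survivors: list[str]
    dropped: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "clusters": self.clusters,
            "survivors": self.survivors,
            "dropped": self.dropped,
        }


def spearman_redundancy_reduce(
    table: FeatureTable, srt: float
) -> tuple[FeatureTable, RedundancyReport]:
    """Collapse Spearman-redundant feature clusters to their highest-variance member.

    Features connected by ``|rho| >= srt`` form clusters (connected
    components of the thresholded graph; transitive closure, so a chain
    A-B-C merges even if A and C are weakly correlated). Per cluster the
    feature with the highest sample variance survives, ties broken by input
    column order. Singletons always survive. Column order is preserved.
    """
    if len(table) < 2:
        raise ConfigurationError("need >= 2 samples for correlation analysis")
    names = table.feature_names
    if not names:
        raise ConfigurationError("need >= 1 feature")
    X = table.X
    p = len(names)
    if p == 1:
        report = RedundancyReport(clusters=[[names[0]]], survivors=[names[0]])
        return table, report

    ranks = stats.rankdata(X, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    # constant columns yield NaN correlations: treat as uncorrelated
    np.fill_diagonal(rho, 1.0)
    adj = np.abs(np.nan_to_num(rho, nan=0.0)) >= srt
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)

    variances = X.var(axis=0, ddof=1)
    clusters: list[list[str]] = [[] for _ in range(n_comp)]
    for j, name in enumerate(names):
        clusters[comp[j]].append(name)

    survivors: list[str] = []
    dropped: dict[str, int] = {}
    for cid in range(n_comp):
        members = clusters[cid]
        idx = [names.index(m) for m in members]
        best = members[int(np.argmax(variances[idx]))]  # argmax is first-wins on ties
        for m in members:
            if m != best:
                dropped[m] = cid
        survivors.append(best)
    survivors = [n for n in names if n not in dropped]  # input column order
    report = RedundancyReport(
        clusters=[c for c in clusters if c], survivors=survivors, dropped=dropped
    )
    return table.select_features(survivors), report


def r2_rank_select(train: FeatureTable, n_select: int) -> list[str]:
    """Top features by R² of the label-on-feature univariate fit, train rows only.

    R² equals the squared Pearson correlation between feature and the 0/1
    label. Returns up to ``n_select`` names, descending R², ties broken by
    input column order. If fewer features are available all are returned
    (zero-padding downstream absorbs the deficit).
    """
    y = train.labels
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ConfigurationError("train set needs >= 2 samples of each class")
    X = train.X
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Xc * yc[:, None]).sum(axis=0) / denom, 0.0)
    r2 = r**2
    order = np.argsort(-r2, kind="stable")
    names = train.feature_names
    return [names[i] for i in order[: min(n_select, len(names))]]


class FeatureScaler:
    """Train-statistics scaler used before amplitude encoding.

    Per feature: z-score with train mean/SD, then min-max map of the
    z-scores to [0, 1] using train extremes (clipping test rows into the
    same range), so the subsequent L2 normalization sees non-negative
    coordinates and amplitude signs do not encode arbitrary centering.
    """

    def fit(self, X_train: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X_train, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.mean_) / self.sd_
        self.zmin_ = Z.min(axis=0)
        zmax = Z.max(axis=0)
        rng = zmax - self.zmin_
        self.zrange_ = np.where(rng > 0, rng, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.sd_
        U = (Z - self.zmin_) / self.zrange_
        return np.clip(U, 0.0, 1.0)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def zero_pad_normalize(x: np.ndarray, target_dim: int) -> np.ndarray:
    """Zero-pad ``x`` to ``target_dim`` and L2-normalize.

    ``target_dim`` must be a power of two (the amplitude register size) and
    at least ``len(x)``. Raises :class:`EncodingError` on an all-zero input,
    which cannot be normalized — rescale the features or drop the row.
    """
    x = np.asarray(x, dtype=float).ravel()
    if target_dim < len(x):
        raise ConfigurationError(f"target_dim {target_dim} < vector length {len(x)}")
    if target_dim < 1 or (target_dim & (target_dim - 1)) != 0:
        raise ConfigurationError("target_dim must be a power of two")
    out = np.zeros(target_dim)
    out[: len(x)] = x
    norm = np.linalg.norm(out)
    if norm == 0.0:
        raise EncodingError(
            "all-zero vector cannot be amplitude-normalized; "
            "check feature scaling or drop degenerate rows"
        )
    return out / norm
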