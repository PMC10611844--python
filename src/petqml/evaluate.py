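"""Performance analytics and geometric-difference advantage scoring.

Balanced accuracy (BACC), the mean of sensitivity and specificity, is the
study's single performance figure; per dataset variant it is averaged over
the ten folds with a normal-approximation 95% confidence half-width
(1.96 * SD / sqrt(10)).

The **geometric difference** compares the geometry induced by the quantum
fidelity kernel with that of a classical reference kernel on the same
samples. With both kernels trace-normalized to trace = n,

    GD_Q = sqrt( || sqrt(K_Q) (K_C + lambda I)^-1 sqrt(K_Q) ||_inf )

(spectral norm, PSD matrix square root). GD_Q > 1 means the classical
kernel cannot reproduce the quantum kernel's geometry — a necessary
precondition for a quantum predictive advantage; GD_Q <= 1 means the data
offers none. The study-level readout correlates GD_Q with
dBACC = qBACC - cBACC across dataset variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._linalg import psd_project
from .errors import DegenerateDataError, SizingError
from .qml import KernelMatrix

__all__ = [
    "ConfusionCounts",
    "FoldResult",
    "VariantSummary",
    "CorrelationResult",
    "confusion_from_predictions",
    "bacc",
    "gd_score",
    "summarize_variant",
    "correlate_gd_dbacc",
    "advantage_rule",
    "QML_METHODS",
    "CML_METHODS",
]

QML_METHODS = ("qsSVM", "qSVM", "qGP", "qNN", "qDC")
CML_METHODS = ("cSVM", "cGP", "cNN", "cKNN")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def bacc(counts: ConfusionCounts) -> float:
    """Balanced accuracy in percent: 100 * (sensitivity + specificity) / 2."""
    pos = counts.TP + counts.FN
    neg = counts.TN + counts.FP
    if pos < 1 or neg < 1:
        raise DegenerateDataError("BACC undefined when a class is absent from the test set")
    return 100.0 * (counts.TP / pos + counts.TN / neg) / 2.0


@dataclass(frozen=True)
class FoldResult:
    cohort: str
    srt: float
    n_select: int
    fold_id: int
    method: str
    counts: ConfusionCounts
    bacc: float


@dataclass
class VariantSummary:
    """Per dataset-variant aggregation across folds and methods."""

    cohort: str
    srt: float
    n_select: int
    method_mean: dict[str, float]
    method_ci: dict[str, float]
    qbacc: float
    cbacc: float
    dbacc: float
    gd_q: float
    gd_per_fold: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def _sqrtm_psd(K: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh((K + K.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return (V * np.sqrt(w)) @ V.T


def gd_score(
    K_classical: KernelMatrix | np.ndarray,
    K_quantum: KernelMatrix | np.ndarray,
    reg: float | None = None,
) -> float:
    """Geometric difference between a classical and a quantum kernel.

    Both kernels are PSD-projected and trace-normalized to trace = n before
    the spectral computation; ``reg`` is the ridge added to the classical
    kernel before inversion (default ``1e-8 * n``). Scale-invariant by
    construction.
    """
    KC = K_classical.values if isinstance(K_classical, KernelMatrix) else np.asarray(K_classical, float)
    KQ = K_quantum.values if isinstance(K_quantum, KernelMatrix) else np.asarray(K_quantum, float)
    if KC.shape != KQ.shape or KC.shape[0] != KC.shape[1]:
        raise SizingError("kernels must be square and of equal shape")
    n = KC.shape[0]
    KC = psd_project((KC + KC.T) / 2.0)
    KQ = psd_project((KQ + KQ.T) / 2.0)
    trC, trQ = np.trace(KC), np.trace(KQ)
    if trC <= 0 or trQ <= 0:
        raise SizingError("kernels must have positive trace")
    KC = KC * (n / trC)
    KQ = KQ * (n / trQ)
    lam = 1e-8 * n if reg is None else reg
    sqKQ = _sqrtm_psd(KQ)
    M = sqKQ @ np.linalg.solve(KC + lam * np.eye(n), sqKQ)
    g2 = np.linalg.eigvalsh((M + M.T) / 2.0).max()
    g = float(np.sqrt(max(g2, 0.0)))
    if not np.isfinite(g):
        raise SizingError("geometric difference is not finite")
    return g


def advantage_rule(gd_q: float) -> str:
    """'advantage_likely' iff GD_Q strictly exceeds 1."""
    if not np.isfinite(gd_q) or gd_q < 0:
        raise ValueError("gd_q must be finite and >= 0")
    return "advantage_likely" if gd_q > 1.0 else "advantage_unlikely"


def summarize_variant(
    fold_results: list[FoldResult],
    gd_per_fold: list[float],
    n_folds: int = 10,
) -> VariantSummary:
    """Aggregate fold results of one dataset variant.

    Per method: mean BACC and the 95% CI half-width 1.96 * SD / sqrt(folds).
    qBACC / cBACC are unweighted means over the quantum / classical method
    families present; dBACC their difference; GD_Q the fold average.
    """
    if not fold_results:
        raise SizingError("no fold results")
    key = fold_results[0]
    methods = sorted({r.method for r in fold_results})
    by_method: dict[str, list[float]] = {m: [] for m in methods}
    for r in fold_results:
        by_method[r.method].append(r.bacc)
    gaps = [m for m, v in by_method.items() if len(v) != n_folds]
    if gaps:
        raise SizingError(f"methods with missing folds: {gaps}")
    mean = {m: float(np.mean(v)) for m, v in by_method.items()}
    ci = {
        m: float(1.96 * np.std(v, ddof=1) / np.sqrt(len(v))) for m, v in by_method.items()
    }
    q = [mean[m] for m in methods if m in QML_METHODS]
    c = [mean[m] for m in methods if m in CML_METHODS]
    qbacc = float(np.mean(q)) if q else float("nan")
    cbacc = float(np.mean(c)) if c else float("nan")
    return VariantSummary(
        cohort=key.cohort,
        srt=key.srt,
        n_select=key.n_select,
        method_mean=mean,
        method_ci=ci,
        qbacc=qbacc,
        cbacc=cbacc,
        dbacc=qbacc - cbacc,
        gd_q=float(np.mean(gd_per_fold)) if gd_per_fold else float("nan"),
        gd_per_fold=list(gd_per_fold),
    )


def correlate_gd_dbacc(summaries: list[VariantSummary]) -> CorrelationResult:
    """Pearson correlation between per-variant GD_Q and dBACC."""
    if len(summaries) < 3:
        raise SizingError("need >= 3 variants for a correlation")
    gd = np.array([s.gd_q for s in summaries])
    db = np.array([s.dbacc for s in summaries])
    if np.ptp(gd) == 0 or np.ptp(db) == 0:
        raise DegenerateDataError("correlation undefined: zero variance")
    res = stats.pearsonr(gd, db)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(summaries))
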