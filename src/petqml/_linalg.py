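"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np


def psd_project(K: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Frobenius-nearest positive semi-definite matrix (eigenvalue clipping).

    For a symmetric ``K`` the nearest PSD matrix under the Frobenius norm is
    obtained by zeroing its negative eigenvalues. Idempotent; raises on
    non-symmetric input.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("psd_project requires a square matrix")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("psd_project requires a symmetric matrix")
    w, V = np.linalg.eigh((K + K.T) / 2.0)
    if w.min() >= -tol:
        return K
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T


def min_eigenvalue(K: np.ndarray) -> float:
    return float(np.linalg.eigvalsh((K + K.T) / 2.0).min())


def rbf_kernel_median_heuristic(
    X: np.ndarray, Y: np.ndarray | None = None, gamma: float | None = None
) -> tuple[np.ndarray, float]:
    """RBF kernel with bandwidth from the median pairwise squared distance of X.

    Returns ``(K, gamma)`` with ``K[i, j] = exp(-gamma * ||x_i - y_j||^2)``
    and ``gamma = 1 / median(||x_i - x_j||^2)`` over distinct pairs of X
    (the standard median heuristic). Pass ``gamma`` to reuse a train-fitted
    bandwidth for test blocks.
    """
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    if gamma is None:
        sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
        vals = sq[np.triu_indices_from(sq, k=1)]
        med = np.median(vals[vals > 0]) if (vals > 0).any() else 1.0
        gamma = 1.0 / med
    D = np.sum((X[:, None, :] - Y[None, :, :]) ** 2, axis=-1)
    return np.exp(-gamma * D), float(gamma)
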