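"""Classical baselines matched to the quantum classifiers.

The four methods mirror their quantum counterparts and consume exactly the
same selected, standardized features as the quantum arm of the same fold
(the fair-comparison contract):

* **cSVM** — RBF-kernel support vector machine, C = 1, bandwidth by the
  median heuristic;
* **cGP** — Gaussian-process regression on +/-1 labels with the RBF kernel
  and sign readout, sharing the solver with qGP so the pair differs only in
  the kernel;
* **cNN** — one-hidden-layer perceptron (16 units);
* **cKNN** — k-nearest-neighbour with k = 5 on Euclidean distance (the
  classical variant of the k = 1 quantum distance classifier).

Hyperparameters are fixed, documented defaults; no per-fold tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from ._linalg import rbf_kernel_median_heuristic
from .errors import DegenerateDataError

__all__ = ["CmlConfig", "fit_predict_cml", "CML_METHODS"]

CML_METHODS = ("cSVM", "cGP", "cNN", "cKNN")


@dataclass(frozen=True)
class CmlConfig:
    """Classical method choice plus its fixed hyperparameters."""

    method: Literal["cSVM", "cGP", "cNN", "cKNN"]
    seed: int = 0
    hyperparameters: dict = field(
        default_factory=lambda: {
            "svm_C": 1.0,
            "gp_sigma2": 0.1,
            "nn_hidden": 16,
            "nn_max_iter": 500,
            "knn_k": 5,
        }
    )

    def __post_init__(self):
        if self.method == "cKNN" and self.hyperparameters.get("knn_k", 5) != 5:
            raise ValueError("cKNN runs with k = 5 by design")


def fit_predict_cml(
    config: CmlConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> np.ndarray:
    """Fit one classical baseline on the fold's features and predict the test rows.

    ``X_train`` / ``X_test`` must be the same selected and scaled features
    the quantum arm encodes (without the zero padding, which carries no
    information).
    """
    y = np.asarray(y_train, dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training labels contain a single class")
    hp = config.hyperparameters
    if config.method == "cSVM":
        K_tr, gamma = rbf_kernel_median_heuristic(X_train)
        model = SVC(C=hp["svm_C"], kernel="precomputed")
        model.fit(K_tr, y)
        K_te, _ = rbf_kernel_median_heuristic(X_test, X_train, gamma=gamma)
        return model.predict(K_te)
    if config.method == "cGP":
        from scipy.linalg import cho_factor, cho_solve

        K_tr, gamma = rbf_kernel_median_heuristic(X_train)
        A = K_tr + hp["gp_sigma2"] * np.eye(len(y))
        alpha = cho_solve(cho_factor(A), 2.0 * y - 1.0)
        K_te, _ = rbf_kernel_median_heuristic(X_test, X_train, gamma=gamma)
        return (K_te @ alpha > 0).astype(int)
    if config.method == "cNN":
        model = MLPClassifier(
            hidden_layer_sizes=(hp["nn_hidden"],),
            max_iter=hp["nn_max_iter"],
            random_state=config.seed,
        )
        model.fit(X_train, y)
        return model.predict(X_test)
    if config.method == "cKNN":
        model = KNeighborsClassifier(n_neighbors=hp["knn_k"])
        model.fit(X_train, y)
        return model.predict(X_test)
    raise ValueError(f"unknown method {config.method!r}")
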