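"""The five quantum classifiers built on amplitude-encoded states.

All five consume the same encoded feature vectors; they differ in how they
use state overlaps:

* **qsSVM** — soft-margin SVM on the precomputed fidelity kernel with the
  regularization fixed at C = 1 (the defining simplification: no
  hyperparameter optimization).
* **qSVM** — same kernel, but C chosen from a grid by inner 5-fold
  patient-grouped cross-validation maximizing balanced accuracy.
* **qGP** — Gaussian-process regression on +/-1 labels with the fidelity
  kernel; prediction is the sign of the posterior mean, and the posterior
  variance uses the test-test kernel block (three kernel evaluations, as
  the swap-test workflow on hardware requires).
* **qNN** — variational circuit: encoded state -> layered Ry/Rz + CNOT-ring
  ansatz -> <Z> on qubit 0; trained by gradient descent with
  parameter-shift gradients on an MSE loss against +/-1 labels.
* **qDC** — 1-nearest-neighbour on the state distance
  d^2 = 2 - 2 Re<test|train>, which needs *signed* overlaps and hence the
  Hadamard test on hardware.

Fidelity kernels use the swap-test estimator (entries |<x|y>|^2), signed
kernels the Hadamard-test estimator (entries Re<x|y>).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.svm import SVC

from ._linalg import min_eigenvalue, psd_project
from .errors import DegenerateDataError, SizingError
from .quantum import (
    CircuitSummary,
    NoiseModel,
    QuantumState,
    ShotConfig,
    hadamard_test_circuit_summary,
    swap_test_circuit_summary,
)

__all__ = [
    "KernelMatrix",
    "QmlModelState",
    "quantum_kernel_matrix",
    "fit_qssvm",
    "predict_qssvm",
    "fit_qsvm",
    "fit_qgp",
    "predict_qgp",
    "fit_qnn",
    "predict_qnn",
    "predict_qdc",
]

QSVM_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class KernelMatrix:
    """Gram matrix of state overlaps with provenance.

    ``estimator='swap'`` entries are fidelities ``|<x|y>|^2`` in [0, 1];
    ``estimator='hadamard'`` entries are signed overlaps ``Re<x|y>`` in
    [-1, 1]. ``provenance`` records whether the entries are analytic
    (``exact``), shot-sampled under noise (``noisy``), or post-mitigation
    (``mitigated``). Noisy kernels may violate range and PSD constraints.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    provenance: Literal["exact", "noisy", "mitigated"]
    estimator: Literal["swap", "hadamard"]

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    def min_eigenvalue(self) -> float:
        if not self.is_square:
            raise SizingError("eigenvalues need a square kernel")
        return min_eigenvalue(self.values)

    def to_csv(self, path) -> None:
        """Persist entries as CSV with provenance header comments."""
        import pandas as pd

        with open(path, "w") as fh:
            fh.write(f"# provenance: {self.provenance}\n# estimator: {self.estimator}\n")
            pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids).to_csv(fh)

    def validate_exact(self, tol: float = 1e-8) -> None:
        """Check the invariants an exact fidelity kernel must satisfy."""
        if self.estimator == "swap":
            if self.values.min() < -1e-10 or self.values.max() > 1 + 1e-10:
                raise ValueError("exact swap kernel entries must lie in [0, 1]")
        if self.is_square:
            if not np.allclose(self.values, self.values.T, atol=1e-10):
                raise ValueError("exact square kernel must be symmetric")
            if self.estimator == "swap":
                if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
                    raise ValueError("exact swap kernel diagonal must be 1")
                if self.min_eigenvalue() < -tol:
                    raise ValueError("exact swap kernel must be PSD")


def _states_to_matrix(states: Sequence[QuantumState]) -> np.ndarray:
    n_qubits = {s.n_qubits for s in states}
    if len(n_qubits) != 1:
        raise SizingError("states mix qubit counts")
    return np.stack([s.amplitudes for s in states])


def quantum_kernel_matrix(
    X: Sequence[QuantumState],
    Y: Sequence[QuantumState] | None = None,
    mode: Literal["exact", "shots"] = "exact",
    estimator: Literal["swap", "hadamard"] = "swap",
    shots: ShotConfig | None = None,
    noise: NoiseModel | None = None,
    circuit: CircuitSummary | None = None,
    row_ids: Sequence[str] | None = None,
    col_ids: Sequence[str] | None = None,
) -> KernelMatrix:
    """Gram matrix of overlaps between two encoded state collections.

    With ``mode='exact'`` entries are analytic; with ``mode='shots'`` every
    entry passes through the depolarizing/readout/binomial measurement
    pipeline (symmetric entries are estimated once and mirrored, matching a
    hardware run that measures each pair once).
    """
    symmetric = Y is None
    A = _states_to_matrix(X)
    B = A if symmetric else _states_to_matrix(Y)
    if not symmetric and X[0].n_qubits != Y[0].n_qubits:
        raise SizingError("X and Y qubit counts differ")
    G = A.conj() @ B.T
    ideal = np.abs(G) ** 2 if estimator == "swap" else G.real

    if row_ids is None:
        row_ids = [f"x{i}" for i in range(len(A))]
    if col_ids is None:
        col_ids = list(row_ids) if symmetric else [f"y{j}" for j in range(len(B))]

    if mode == "exact":
        return KernelMatrix(
            values=ideal.astype(float),
            row_ids=list(row_ids),
            col_ids=list(col_ids),
            provenance="exact",
            estimator=estimator,
        )

    if shots is None:
        raise SizingError("shot mode requires a ShotConfig")
    noise = noise or NoiseModel.noiseless()
    if circuit is None:
        n_q = X[0].n_qubits
        circuit = (
            swap_test_circuit_summary(n_q)
            if estimator == "swap"
            else hadamard_test_circuit_summary(n_q)
        )
    lam = noise.effective_lambda(circuit)
    eps = noise.readout_eps
    p0 = (1.0 + ideal) / 2.0
    p = (1.0 - lam) * p0 + lam / 2.0
    p = p * (1.0 - eps) + (1.0 - p) * eps
    p = np.clip(p, 0.0, 1.0)  # guard float rounding at the endpoints
    rng = np.random.default_rng(shots.seed)
    est = 2.0 * rng.binomial(shots.shots, p) / shots.shots - 1.0
    if symmetric:
        est = np.triu(est) + np.triu(est, k=1).T  # one estimate per pair
    return KernelMatrix(
        values=est,
        row_ids=list(row_ids),
        col_ids=list(col_ids),
        provenance="noisy",
        estimator=estimator,
    )


@dataclass
class QmlModelState:
    """Fitted state of one quantum classifier."""

    method: Literal["qsSVM", "qSVM", "qGP", "qNN", "qDC"]
    params: dict = field(default_factory=dict)
    training_sample_ids: list[str] = field(default_factory=list)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError("training labels contain a single class")
    return labels


def _prepare_square_kernel(K: KernelMatrix) -> np.ndarray:
    """Symmetrize/PSD-repair a training kernel when noise broke its structure."""
    if not K.is_square:
        raise SizingError("training kernel must be square with row_ids == col_ids")
    values = K.values
    if K.provenance != "exact":
        values = (values + values.T) / 2.0
        if min_eigenvalue(values) < -1e-8:
            warnings.warn(
                "non-PSD training kernel; applying PSD projection", RuntimeWarning
            )
            values = psd_project(values)
    return values


# --------------------------------------------------------------------------
# qsSVM / qSVM
# --------------------------------------------------------------------------

def fit_qssvm(K_train: KernelMatrix, labels: np.ndarray) -> QmlModelState:
    """Simplified quantum kernel SVM: precomputed fidelity kernel, fixed C=1."""
    y = _check_binary(labels)
    G = _prepare_square_kernel(K_train)
    svc = SVC(C=1.0, kernel="precomputed")
    svc.fit(G, y)
    return QmlModelState(
        method="qsSVM",
        params={"svc": svc, "C": 1.0},
        training_sample_ids=list(K_train.row_ids),
    )


def predict_qssvm(state: QmlModelState, K_test_train: KernelMatrix) -> np.ndarray:
    if list(K_test_train.col_ids) != state.training_sample_ids:
        raise SizingError("test kernel columns must match training samples")
    return state.params["svc"].predict(K_test_train.values)


def _grouped_folds(
    groups: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random patient-grouped fold assignment: list of validation index arrays."""
    uniq = list(dict.fromkeys(groups))
    order = rng.permutation(len(uniq))
    assignment = {uniq[j]: i % n_folds for i, j in enumerate(order)}
    fold_of = np.array([assignment[g] for g in groups])
    return [np.flatnonzero(fold_of == f) for f in range(n_folds)]


def fit_qsvm(
    K_train: KernelMatrix,
    labels: np.ndarray,
    inner_cv_seed: int,
    groups: np.ndarray | None = None,
) -> QmlModelState:
    """Quantum kernel SVM with C tuned by inner patient-grouped 5-fold CV.

    ``groups`` are the patient ids of the training samples; when omitted
    every sample is its own group. The C maximizing mean inner balanced
    accuracy is selected (first grid entry wins ties).
    """
    y = _check_binary(labels)
    G = _prepare_square_kernel(K_train)
    n = len(y)
    if groups is None:
        groups = np.asarray(K_train.row_ids)
    groups = np.asarray(groups)
    rng = np.random.default_rng(inner_cv_seed)
    folds = _grouped_folds(groups, 5, rng)

    scores = []
    for C in QSVM_C_GRID:
        fold_scores = []
        for val_idx in folds:
            if len(val_idx) == 0:
                continue
            tr_idx = np.setdiff1d(np.arange(n), val_idx)
            if len(np.unique(y[tr_idx])) < 2 or len(np.unique(y[val_idx])) < 2:
                continue
            svc = SVC(C=C, kernel="precomputed")
            svc.fit(G[np.ix_(tr_idx, tr_idx)], y[tr_idx])
            pred = svc.predict(G[np.ix_(val_idx, tr_idx)])
            fold_scores.append(balanced_accuracy_score(y[val_idx], pred))
        scores.append(np.mean(fold_scores) if fold_scores else -np.inf)
    best_C = QSVM_C_GRID[int(np.argmax(scores))]
    svc = SVC(C=best_C, kernel="precomputed")
    svc.fit(G, y)
    return QmlModelState(
        method="qSVM",
        params={"svc": svc, "C": best_C, "inner_scores": dict(zip(QSVM_C_GRID, scores))},
        training_sample_ids=list(K_train.row_ids),
    )


predict_qsvm = predict_qssvm  # identical prediction path, different fitted C


# --------------------------------------------------------------------------
# qGP
# --------------------------------------------------------------------------

def fit_qgp(
    K_train: KernelMatrix, labels: np.ndarray, sigma2: float = 0.1
) -> QmlModelState:
    """GP regression on +/-1 labels with the fidelity kernel plus noise sigma2."""
    y01 = _check_binary(labels)
    y = 2.0 * y01 - 1.0
    G = _prepare_square_kernel(K_train)
    A = G + sigma2 * np.eye(len(y))
    try:
        from scipy.linalg import cho_factor, cho_solve

        cf = cho_factor(A)
        alpha = cho_solve(cf, y)
    except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
        raise DegenerateDataError(
            f"K + sigma2*I not invertible ({e}); increase sigma2 jitter"
        ) from e
    return QmlModelState(
        method="qGP",
        params={"alpha": alpha, "A": A, "sigma2": sigma2},
        training_sample_ids=list(K_train.row_ids),
    )


def predict_qgp(
    state: QmlModelState,
    K_test_train: KernelMatrix,
    K_test_test: KernelMatrix,
) -> np.ndarray:
    """Sign of the posterior mean; posterior variance is computed and stored.

    The variance uses the test-test kernel block, honoring the
    three-kernel-evaluation structure of the hardware workflow.
    """
    if list(K_test_train.col_ids) != state.training_sample_ids:
        raise SizingError("test kernel columns must match training samples")
    Kst = K_test_train.values
    mean = Kst @ state.params["alpha"]
    from scipy.linalg import cho_factor, cho_solve

    cf = cho_factor(state.params["A"])
    v = cho_solve(cf, Kst.T)
    var = np.diag(K_test_test.values) - np.sum(Kst * v.T, axis=1)
    state.params["last_posterior_mean"] = mean
    state.params["last_posterior_var"] = var
    return (mean > 0).astype(int)


# --------------------------------------------------------------------------
# qNN
# --------------------------------------------------------------------------

def _batch_apply_ansatz(theta: np.ndarray, layout: tuple[int, int], Psi: np.ndarray) -> np.ndarray:
    """Apply the Ry/Rz + CNOT-ring ansatz to a batch of statevectors.

    ``Psi`` has shape (n_samples, 2**n_qubits); qubit 0 is the most
    significant bit, matching :func:`petqml.quantum.apply_ansatz`.
    """
    n_qubits, n_layers = layout
    m = Psi.shape[0]
    psi = Psi.reshape((m,) + (2,) * n_qubits).astype(complex)
    i = 0
    for _ in range(n_layers):
        for q in range(n_qubits):
            ax = q + 1
            c, s = np.cos(theta[i] / 2), np.sin(theta[i] / 2)
            a0 = np.take(psi, 0, axis=ax)
            a1 = np.take(psi, 1, axis=ax)
            psi = np.stack([c * a0 - s * a1, s * a0 + c * a1], axis=ax)
            e0, e1 = np.exp(-0.5j * theta[i + 1]), np.exp(0.5j * theta[i + 1])
            a0 = np.take(psi, 0, axis=ax) * e0
            a1 = np.take(psi, 1, axis=ax) * e1
            psi = np.stack([a0, a1], axis=ax)
            i += 2
        if n_qubits >= 2:
            for q in range(n_qubits):
                tgt = (q + 1) % n_qubits
                cax, tax = q + 1, tgt + 1
                idx0 = [slice(None)] * psi.ndim
                idx1 = [slice(None)] * psi.ndim
                idx0[cax], idx1[cax] = 1, 1
                idx0[tax], idx1[tax] = 0, 1
                block0 = psi[tuple(idx0)].copy()
                psi[tuple(idx0)] = psi[tuple(idx1)]
                psi[tuple(idx1)] = block0
    return psi.reshape(m, -1)


def _qnn_expectation(theta: np.ndarray, layout: tuple[int, int], Psi: np.ndarray) -> np.ndarray:
    """<Z> on qubit 0 after the ansatz, per sample."""
    out = _batch_apply_ansatz(theta, layout, Psi)
    probs = np.abs(out) ** 2
    half = out.shape[1] // 2
    return probs[:, :half].sum(axis=1) - probs[:, half:].sum(axis=1)


def qnn_loss_and_grad(
    theta: np.ndarray, layout: tuple[int, int], Psi: np.ndarray, y_pm: np.ndarray
) -> tuple[float, np.ndarray]:
    """MSE loss against +/-1 labels and its parameter-shift gradient.

    Every ansatz angle generates a Pauli rotation, so the exact gradient of
    the expectation is ``(f(theta + pi/2) - f(theta - pi/2)) / 2``.
    """
    z = _qnn_expectation(theta, layout, Psi)
    resid = z - y_pm
    loss = float(np.mean(resid**2))
    grad = np.empty_like(theta)
    for k in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += np.pi / 2
        tm[k] -= np.pi / 2
        dz = (_qnn_expectation(tp, layout, Psi) - _qnn_expectation(tm, layout, Psi)) / 2
        grad[k] = float(np.mean(2.0 * resid * dz))
    return loss, grad


def fit_qnn(
    train_states: Sequence[QuantumState],
    labels: np.ndarray,
    layout: tuple[int, int] | None = None,
    epochs: int = 120,
    lr: float = 0.3,
    seed: int = 0,
) -> QmlModelState:
    """Train the variational classifier by full-batch gradient descent."""
    y = _check_binary(labels)
    y_pm = 2.0 * y - 1.0
    Psi = _states_to_matrix(train_states)
    n_qubits = train_states[0].n_qubits
    if layout is None:
        layout = (n_qubits, 2)
    if layout[0] != n_qubits:
        raise SizingError("layout does not match state qubit count")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(-0.1, 0.1, size=2 * layout[0] * layout[1])
    for _ in range(epochs):
        loss, grad = qnn_loss_and_grad(theta, layout, Psi, y_pm)
        if not np.isfinite(loss):
            raise DegenerateDataError(f"non-finite qNN loss (theta norm {np.linalg.norm(theta):.3g})")
        theta = theta - lr * grad
    return QmlModelState(
        method="qNN",
        params={"theta": theta, "layout": layout, "final_loss": loss},
        training_sample_ids=[],
    )


def predict_qnn(state: QmlModelState, test_states: Sequence[QuantumState]) -> np.ndarray:
    Psi = _states_to_matrix(test_states)
    z = _qnn_expectation(state.params["theta"], state.params["layout"], Psi)
    return (z > 0).astype(int)


# --------------------------------------------------------------------------
# qDC
# --------------------------------------------------------------------------

def predict_qdc(
    train_states: Sequence[QuantumState],
    train_labels: np.ndarray,
    test_states: Sequence[QuantumState],
    mode: Literal["exact", "shots"] = "exact",
    shots: ShotConfig | None = None,
    noise: NoiseModel | None = None,
    K_test_train: KernelMatrix | None = None,
) -> np.ndarray:
    """Quantum distance classifier: 1-NN on d^2 = 2 - 2 Re<test|train>.

    The signed overlap comes from the Hadamard test (sign preservation is
    the reason this classifier cannot use the swap test). A precomputed
    (possibly mitigated) signed kernel can be supplied via ``K_test_train``.
    Ties go to the lowest training index.
    """
    y = np.asarray(train_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("qDC needs at least one training sample per class")
    if K_test_train is None:
        K_test_train = quantum_kernel_matrix(
            test_states,
            train_states,
            mode=mode,
            estimator="hadamard",
            shots=shots,
            noise=noise,
        )
    if K_test_train.estimator != "hadamard":
        raise SizingError("qDC requires signed (hadamard) overlaps")
    d2 = 2.0 - 2.0 * K_test_train.values
    nearest = np.argmin(d2, axis=1)  # argmin returns the first (lowest) index on ties
    return y[nearest]
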