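"""Learning-based quantum error mitigation.

On noisy hardware the measured overlap estimates are systematically
distorted (depolarizing shrinkage toward the maximally mixed outcome plus
readout bias) and statistically noisy (finite shots). Mitigation is cast as
a supervised regression problem: on a calibration set of training-state
pairs, record both the analytic (noiseless-simulator) overlap and one noisy
shot estimate, fit an ensemble-of-trees regression from noisy to noiseless
values, and map every kernel entry through it. Calibration pairs are drawn
only from training-set states, so no test information leaks into the
mitigator.

After the entrywise regression the kernel is range-clipped, symmetrized and
(for fidelity kernels) projected to the nearest positive semi-definite
matrix — the regression is entrywise and cannot enforce matrix-level
constraints itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from ._linalg import psd_project
from .errors import SizingError
from .qml import KernelMatrix
from .quantum import (
    CircuitSummary,
    NoiseModel,
    QuantumState,
    ShotConfig,
    exact_overlap,
    hadamard_test_circuit_summary,
    hadamard_test_estimate,
    swap_test_circuit_summary,
    swap_test_estimate,
)

__all__ = [
    "CalibrationSet",
    "EmModel",
    "build_calibration",
    "fit_em",
    "mitigate_kernel",
    "psd_project",
]


@dataclass
class CalibrationSet:
    """Paired noisy / noiseless overlap records from training states only."""

    estimator: Literal["swap", "hadamard"]
    pair_ids: list[tuple[int, int]]
    noisy: np.ndarray
    noiseless: np.ndarray
    n_one_qubit_gates: int
    n_two_qubit_gates: int
    shots: int

    def __len__(self) -> int:
        return len(self.pair_ids)

    def to_csv(self, path) -> None:
        """Persist calibration records (pair, noisy, noiseless, circuit, shots)."""
        import pandas as pd

        pd.DataFrame(
            {
                "pair_i": [i for i, _ in self.pair_ids],
                "pair_j": [j for _, j in self.pair_ids],
                "noisy": self.noisy,
                "noiseless": self.noiseless,
                "n1": self.n_one_qubit_gates,
                "n2": self.n_two_qubit_gates,
                "shots": self.shots,
            }
        ).to_csv(path, index=False)

    def to_records(self) -> np.ndarray:
        """Feature matrix the mitigation regression consumes."""
        n = len(self)
        return np.column_stack(
            [
                self.noisy,
                np.full(n, self.n_one_qubit_gates, dtype=float),
                np.full(n, self.n_two_qubit_gates, dtype=float),
                np.full(n, self.shots, dtype=float),
            ]
        )


@dataclass
class EmModel:
    """Fitted noisy-to-noiseless regression for one estimator type."""

    estimator: Literal["swap", "hadamard"]
    regressor: RandomForestRegressor
    n_records: int
    oob_residual_sd: float | None
    calib_circuit: CircuitSummary | None = None
    calib_shots: int | None = None

    def apply(self, noisy: np.ndarray, circuit: CircuitSummary, shots: int) -> np.ndarray:
        noisy = np.asarray(noisy, dtype=float).ravel()
        X = np.column_stack(
            [
                noisy,
                np.full(len(noisy), circuit.n_one_qubit_gates, dtype=float),
                np.full(len(noisy), circuit.n_two_qubit_gates, dtype=float),
                np.full(len(noisy), shots, dtype=float),
            ]
        )
        return self.regressor.predict(X)


def build_calibration(
    train_states: Sequence[QuantumState],
    n_pairs: int,
    estimator: Literal["swap", "hadamard"],
    shots: ShotConfig,
    noise: NoiseModel,
    seed: int,
    circuit: CircuitSummary | None = None,
) -> CalibrationSet:
    """Sample state pairs from train x train and record noisy + analytic values.

    Pairs are drawn uniformly with replacement; each record holds one
    shot-sampled noisy estimate and the analytic overlap, plus the circuit
    metadata the regression uses as auxiliary inputs.
    """
    if len(train_states) < 2:
        raise SizingError("calibration needs >= 2 training states")
    if n_pairs < 50:
        warnings.warn(
            f"{n_pairs} calibration pairs is few; the regression may be unstable",
            RuntimeWarning,
        )
    n_q = train_states[0].n_qubits
    if circuit is None:
        circuit = (
            swap_test_circuit_summary(n_q)
            if estimator == "swap"
            else hadamard_test_circuit_summary(n_q)
        )
    rng = np.random.default_rng(seed)
    m = len(train_states)
    ii = rng.integers(0, m, size=n_pairs)
    jj = rng.integers(0, m, size=n_pairs)
    estimate = swap_test_estimate if estimator == "swap" else hadamard_test_estimate
    noisy = np.empty(n_pairs)
    truth = np.empty(n_pairs)
    for k, (i, j) in enumerate(zip(ii, jj)):
        a, b = train_states[i], train_states[j]
        ov = exact_overlap(a, b)
        truth[k] = abs(ov) ** 2 if estimator == "swap" else ov.real
        noisy[k] = float(estimate(a, b, shots, noise, circuit, rng=rng))
    return CalibrationSet(
        estimator=estimator,
        pair_ids=list(zip(ii.tolist(), jj.tolist())),
        noisy=noisy,
        noiseless=truth,
        n_one_qubit_gates=circuit.n_one_qubit_gates,
        n_two_qubit_gates=circuit.n_two_qubit_gates,
        shots=shots.shots,
    )


def fit_em(calibration: CalibrationSet, seed: int = 0) -> EmModel:
    """Fit the ensemble-of-trees noisy-to-noiseless regression (200 trees)."""
    if len(calibration) < 50:
        raise SizingError("need >= 50 calibration records to fit the mitigator")
    if np.ptp(calibration.noiseless) == 0:
        warnings.warn("constant calibration targets; mitigator is degenerate", RuntimeWarning)
    reg = RandomForestRegressor(
        n_estimators=200, random_state=seed, oob_score=True, bootstrap=True
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # oob_score warns on tiny sets
        reg.fit(calibration.to_records(), calibration.noiseless)
    oob_sd = None
    if hasattr(reg, "oob_prediction_"):
        oob_sd = float(np.std(reg.oob_prediction_ - calibration.noiseless))
    return EmModel(
        estimator=calibration.estimator,
        regressor=reg,
        n_records=len(calibration),
        oob_residual_sd=oob_sd,
        calib_circuit=CircuitSummary(
            n_one_qubit_gates=calibration.n_one_qubit_gates,
            n_two_qubit_gates=calibration.n_two_qubit_gates,
        ),
        calib_shots=calibration.shots,
    )


def mitigate_kernel(
    K_noisy: KernelMatrix,
    em: EmModel,
    circuit: CircuitSummary | None = None,
    shots: int | None = None,
) -> KernelMatrix:
    """Map every kernel entry through the mitigation regression and repair.

    Entries are regressed, range-clipped ([0, 1] for fidelity kernels,
    [-1, 1] for signed kernels), symmetrized when square, and — for
    fidelity kernels — PSD-projected. ``circuit``/``shots`` default to the
    calibration's metadata.
    """
    if K_noisy.provenance != "noisy":
        raise SizingError("mitigate_kernel expects a noisy-provenance kernel")
    if em.estimator != K_noisy.estimator:
        raise SizingError(
            f"mitigator trained for {em.estimator!r} cannot mitigate {K_noisy.estimator!r}"
        )
    circuit = circuit or em.calib_circuit
    shots = shots or em.calib_shots
    if circuit is None or shots is None:
        raise SizingError("circuit metadata and shots required for mitigation")
    vals = em.apply(K_noisy.values.ravel(), circuit, shots).reshape(
        K_noisy.values.shape
    )
    lo, hi = (0.0, 1.0) if K_noisy.estimator == "swap" else (-1.0, 1.0)
    vals = np.clip(vals, lo, hi)
    if K_noisy.is_square:
        vals = (vals + vals.T) / 2.0
        if K_noisy.estimator == "swap":
            vals = psd_project(vals)
    return KernelMatrix(
        values=vals,
        row_ids=list(K_noisy.row_ids),
        col_ids=list(K_noisy.col_ids),
        provenance="mitigated",
        estimator=K_noisy.estimator,
    )
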