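"""Learned error mitigation: calibration, regression, kernel repair."""

import numpy as np
import pytest

from conftest import random_states
from petqml.errors import SizingError
from petqml.mitigation import (
    CalibrationSet,
    build_calibration,
    fit_em,
    mitigate_kernel,
    psd_project,
)
from petqml.qml import quantum_kernel_matrix
from petqml.quantum import CircuitSummary, NoiseModel, ShotConfig


class TestPsdProject:
    def test_psd_input_unchanged(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((6, 6))
        K = A @ A.T
        assert np.allclose(psd_project(K), K, atol=1e-12)

    def test_hand_case(self):
        K = np.diag([1.0, -0.5])
        assert np.allclose(psd_project(K), np.diag([1.0, 0.0]))

    def test_frobenius_nearest_and_idempotent(self):
        """Higham characterization: P = V max(w,0) V^T minimizes ||K - P||_F."""
        rng = np.random.default_rng(1)
        A = rng.standard_normal((10, 10))
        K = (A + A.T) / 2
        P = psd_project(K)
        assert np.linalg.eigvalsh(P).min() >= -1e-10
        assert np.allclose(psd_project(P), P, atol=1e-10)
        # any PSD perturbation of P is farther from K
        w, V = np.linalg.eigh(K)
        manual = (V * np.clip(w, 0, None)) @ V.T
        assert np.allclose(P, manual, atol=1e-10)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            psd_project(np.array([[1.0, 2.0], [0.0, 1.0]]))


NOISE = NoiseModel(p1=0.0, p2=0.005, readout_eps=0.01)
CIRC30 = CircuitSummary(n_one_qubit_gates=0, n_two_qubit_gates=30)


class TestCalibration:
    def test_record_count_and_determinism(self):
        states = random_states(10, 8, seed=2)
        cal = build_calibration(states, 200, "swap", ShotConfig(1000, 0), NOISE, seed=3)
        cal2 = build_calibration(states, 200, "swap", ShotConfig(1000, 0), NOISE, seed=3)
        assert len(cal) == 200
        assert np.array_equal(cal.noisy, cal2.noisy)

    def test_identical_pair_has_unit_truth(self):
        states = random_states(3, 8, seed=4)
        cal = build_calibration(states, 500, "swap", ShotConfig(1000, 0), NOISE, seed=5)
        same = [k for k, (i, j) in enumerate(cal.pair_ids) if i == j]
        assert same and np.allclose(cal.noiseless[same], 1.0)

    def test_zero_noise_high_shots_tracks_truth(self):
        states = random_states(8, 8, seed=6)
        cal = build_calibration(
            states, 200, "swap", ShotConfig(1_000_000, 0), NoiseModel.noiseless(), seed=7
        )
        assert np.mean(np.abs(cal.noisy - cal.noiseless)) <= 2e-3

    def test_few_pairs_warns(self):
        states = random_states(4, 8, seed=8)
        with pytest.warns(RuntimeWarning):
            build_calibration(states, 20, "swap", ShotConfig(100, 0), NOISE, seed=9)


class TestFitEm:
    def test_recovers_known_affine_distortion(self):
        """noisy = 0.8*true + 0.1 + eps: held-out RMSE <= 0.02."""
        rng = np.random.default_rng(10)
        true = rng.uniform(0, 1, 2500)
        noisy = 0.8 * true + 0.1 + rng.normal(0, 0.01, 2500)
        cal = CalibrationSet(
            estimator="swap",
            pair_ids=[(0, 0)] * 2000,
            noisy=noisy[:2000],
            noiseless=true[:2000],
            n_one_qubit_gates=0,
            n_two_qubit_gates=30,
            shots=1000,
        )
        em = fit_em(cal, seed=0)
        pred = em.apply(noisy[2000:], CIRC30, 1000)
        rmse = np.sqrt(np.mean((pred - true[2000:]) ** 2))
        assert rmse <= 0.02

    def test_zero_noise_mitigation_near_identity(self):
        """With no systematic error the mitigator stays near the shot floor."""
        states = random_states(12, 8, seed=11)
        shots = 4096
        cal = build_calibration(
            states, 1500, "swap", ShotConfig(shots, 1), NoiseModel.noiseless(), seed=12
        )
        em = fit_em(cal, seed=1)
        hold = build_calibration(
            states, 400, "swap", ShotConfig(shots, 2), NoiseModel.noiseless(), seed=13
        )
        pred = em.apply(hold.noisy, CIRC30, shots)
        rmse = np.sqrt(np.mean((pred - hold.noiseless) ** 2))
        p0 = (1 + hold.noiseless) / 2
        floor = np.sqrt(np.mean(4 * p0 * (1 - p0) / shots))
        assert rmse <= 2 * max(floor, 1e-3)

    def test_too_few_records_rejected(self):
        cal = CalibrationSet(
            estimator="swap", pair_ids=[(0, 0)] * 10, noisy=np.zeros(10),
            noiseless=np.zeros(10), n_one_qubit_gates=0, n_two_qubit_gates=0, shots=10,
        )
        with pytest.raises(SizingError):
            fit_em(cal)


class TestMitigateKernel:
    def _noisy_setup(self, noise, shots=2048, n=14, seed=20):
        states = random_states(n, 8, seed=seed)
        ids = [f"s{i}" for i in range(n)]
        K_exact = quantum_kernel_matrix(states, row_ids=ids)
        K_noisy = quantum_kernel_matrix(
            states, mode="shots", shots=ShotConfig(shots, seed + 1),
            noise=noise, circuit=CIRC30, row_ids=ids,
        )
        cal = build_calibration(
            states, 1000, "swap", ShotConfig(shots, seed + 2), noise,
            seed=seed + 3, circuit=CIRC30,
        )
        em = fit_em(cal, seed=0)
        return K_exact, K_noisy, em

    def test_strong_depolarizing_mse_reduction(self):
        """lambda ~ 0.2: mitigation cuts kernel-entry MSE by >= 5x."""
        noise = NoiseModel(p1=0.0, p2=0.0074, readout_eps=0.0)  # 1-0.9926^30 ~ 0.2
        K_exact, K_noisy, em = self._noisy_setup(noise)
        K_mit = mitigate_kernel(K_noisy, em)
        mse_noisy = np.mean((K_noisy.values - K_exact.values) ** 2)
        mse_mit = np.mean((K_mit.values - K_exact.values) ** 2)
        assert mse_mit <= mse_noisy / 5

    def test_mitigated_kernel_is_psd_and_in_range(self):
        K_exact, K_noisy, em = self._noisy_setup(NOISE, seed=30)
        K_mit = mitigate_kernel(K_noisy, em)
        assert K_mit.provenance == "mitigated"
        assert K_mit.values.min() >= 0.0 and K_mit.values.max() <= 1.0
        assert K_mit.min_eigenvalue() >= -1e-10

    def test_estimator_mismatch_rejected(self):
        K_exact, K_noisy, em = self._noisy_setup(NOISE, seed=40)
        K_noisy.estimator = "hadamard"
        with pytest.raises(SizingError):
            mitigate_kernel(K_noisy, em)

    def test_exact_kernel_rejected(self):
        K_exact, K_noisy, em = self._noisy_setup(NOISE, seed=50)
        with pytest.raises(SizingError):
            mitigate_kernel(K_exact, em)

    def test_train_only_calibration(self):
        """Calibration records do not depend on any test-set state."""
        states = random_states(10, 8, seed=60)
        cal_all = build_calibration(states[:8], 300, "swap", ShotConfig(512, 0), NOISE, seed=61)
        cal_again = build_calibration(states[:8], 300, "swap", ShotConfig(512, 0), NOISE, seed=61)
        assert np.array_equal(cal_all.noisy, cal_again.noisy)
        assert all(i < 8 and j < 8 for i, j in cal_all.pair_ids)
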