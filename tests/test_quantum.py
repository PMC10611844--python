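"""Statevector simulation: encoding, overlap tests, noise, ansatz."""

import numpy as np
import pytest

from conftest import random_states
from petqml.errors import EncodingError, SizingError
from petqml.quantum import (
    AnsatzParams,
    CircuitSummary,
    NoiseModel,
    QuantumState,
    ShotConfig,
    amplitude_encode,
    ansatz_gate_counts,
    apply_ansatz,
    exact_overlap,
    hadamard_test_estimate,
    optimize_state_prep,
    swap_test_estimate,
)


class TestAmplitudeEncode:
    @pytest.mark.parametrize("length,n_qubits", [(2, 1), (8, 3), (16, 4)])
    def test_qubit_count(self, length, n_qubits):
        x = np.zeros(length)
        x[0] = 1.0
        assert amplitude_encode(x).n_qubits == n_qubits

    def test_basis_state(self):
        s = amplitude_encode([1, 0, 0, 0, 0, 0, 0, 0])
        assert np.allclose(s.amplitudes, np.eye(8)[0])

    def test_rejects_non_unit_norm(self):
        with pytest.raises(EncodingError):
            amplitude_encode(np.ones(4))

    def test_rejects_non_power_of_two(self):
        with pytest.raises(SizingError):
            amplitude_encode(np.array([1.0, 0.0, 0.0]))


class TestExactOverlap:
    def test_self_overlap_is_one(self):
        (s,) = random_states(1, 8, seed=0, complex_valued=True)
        assert np.isclose(exact_overlap(s, s).real, 1.0)

    def test_orthogonal_basis_states(self):
        a = amplitude_encode(np.eye(4)[0])
        b = amplitude_encode(np.eye(4)[1])
        assert exact_overlap(a, b) == 0

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            u = rng.standard_normal(8) + 1j * rng.standard_normal(8)
            v = rng.standard_normal(8) + 1j * rng.standard_normal(8)
            u, v = u / np.linalg.norm(u), v / np.linalg.norm(v)
            a, b = amplitude_encode(u), amplitude_encode(v)
            assert abs(exact_overlap(a, b) - np.vdot(u, v)) < 1e-12

    def test_dimension_mismatch(self):
        a = amplitude_encode(np.eye(4)[0])
        b = amplitude_encode(np.eye(8)[0])
        with pytest.raises(SizingError):
            exact_overlap(a, b)


NOISELESS = NoiseModel.noiseless()
CIRC = CircuitSummary(n_one_qubit_gates=10, n_two_qubit_gates=5)


class TestShotEstimators:
    def test_swap_identical_states_noiseless_gives_one(self):
        (s,) = random_states(1, 8, seed=2)
        est = swap_test_estimate(s, s, ShotConfig(shots=100, seed=0), NOISELESS, CIRC)
        assert est == 1.0  # p0 = 1 exactly, every shot lands on 0

    def test_hadamard_sign_preserved(self):
        (s,) = random_states(1, 8, seed=3)
        neg = QuantumState(amplitudes=-s.amplitudes, n_qubits=s.n_qubits)
        est = hadamard_test_estimate(s, neg, ShotConfig(shots=200, seed=1), NOISELESS, CIRC)
        assert est == -1.0  # Re<a|-a> = -1, p0 = 0 exactly

    def test_swap_estimator_unbiased(self):
        a, b = random_states(2, 8, seed=4)
        truth = abs(exact_overlap(a, b)) ** 2
        ests = swap_test_estimate(
            a, b, ShotConfig(shots=1000, seed=5), NOISELESS, CIRC, size=4000
        )
        se = np.sqrt(np.var(ests) / len(ests))
        assert abs(np.mean(ests) - truth) < 4 * se + 1e-3

    def test_hadamard_binomial_error_bound(self):
        """3x binomial-standard-error band covers ~99% of estimates."""
        a, b = random_states(2, 8, seed=6)
        truth = exact_overlap(a, b).real
        shots = 10_000
        ests = hadamard_test_estimate(
            a, b, ShotConfig(shots=shots, seed=7), NOISELESS, CIRC, size=2000
        )
        p0 = (1.0 + truth) / 2.0
        bound = 3.0 * 2.0 * np.sqrt(p0 * (1 - p0) / shots)  # SE of 2*p_hat - 1
        coverage = np.mean(np.abs(ests - truth) <= bound)
        assert coverage >= 0.98

    def test_depolarized_orthogonal_pair_centered_at_zero(self):
        """Closed-form: lambda = 1-0.99^30; orthogonal pair stays centered at 0."""
        noise = NoiseModel(p1=0.0, p2=0.01, readout_eps=0.0)
        circ = CircuitSummary(n_one_qubit_gates=0, n_two_qubit_gates=30)
        lam = noise.effective_lambda(circ)
        assert np.isclose(lam, 1 - 0.99**30)
        a = amplitude_encode(np.eye(8)[0])
        b = amplitude_encode(np.eye(8)[1])
        # p0 = 0.5 for orthogonal pair; depolarizing keeps p at 0.5 => E[F] = 0
        ests = swap_test_estimate(
            a, b, ShotConfig(shots=1000, seed=8), noise, circ, size=10_000
        )
        se = np.sqrt(np.var(ests) / len(ests))
        assert abs(np.mean(ests)) < 3 * se

    def test_noise_interpolation_endpoints(self):
        a, b = random_states(2, 4, seed=9)
        cfg = ShotConfig(shots=500, seed=10)
        clean = swap_test_estimate(a, b, cfg, NOISELESS, CIRC, size=1000)
        zero_lambda = swap_test_estimate(
            a, b, cfg, NoiseModel(p1=0.0, p2=0.0, readout_eps=0.0), CIRC, size=1000
        )
        assert np.array_equal(clean, zero_lambda)
        # lambda = 1: distribution centered at readout-flipped 0.5
        full = NoiseModel(p1=0.0, p2=0.5, readout_eps=0.0)
        big = CircuitSummary(n_one_qubit_gates=0, n_two_qubit_gates=200)
        ests = swap_test_estimate(a, b, cfg, full, big, size=5000)
        assert abs(np.mean(ests)) < 0.03


class TestAnsatz:
    def test_gate_counts_3q_2l(self):
        c = ansatz_gate_counts(3, 2)
        assert (c.n_one_qubit_gates, c.n_two_qubit_gates) == (12, 6)

    def test_identity_angles_permute_only(self):
        (s,) = random_states(1, 8, seed=11)
        params = AnsatzParams(theta=np.zeros(12), layout=(3, 2))
        out = apply_ansatz(params, s)
        # zero rotations leave only CNOT rings: amplitudes are permuted
        assert np.isclose(np.linalg.norm(out.amplitudes), 1.0)
        assert sorted(np.abs(out.amplitudes).round(12)) == pytest.approx(
            sorted(np.abs(s.amplitudes).round(12))
        )

    def test_unitarity_random_angles(self):
        rng = np.random.default_rng(12)
        (s,) = random_states(1, 16, seed=13, complex_valued=True)
        params = AnsatzParams(theta=rng.uniform(-np.pi, np.pi, 16), layout=(4, 2))
        out = apply_ansatz(params, s)
        assert abs(np.vdot(out.amplitudes, out.amplitudes).real - 1.0) < 1e-12

    def test_single_qubit_ry_pi_flips(self):
        zero = amplitude_encode([1.0, 0.0])
        params = AnsatzParams(theta=np.array([np.pi, 0.0]), layout=(1, 1))
        out = apply_ansatz(params, zero)
        assert np.allclose(np.abs(out.amplitudes), [0.0, 1.0], atol=1e-12)


class TestStatePrep:
    def test_zero_state_trivial(self):
        target = amplitude_encode(np.eye(8)[0])
        _, infid, _ = optimize_state_prep(target, layout=(3, 1), tol=1e-6)
        assert infid <= 1e-6

    def test_random_real_target_three_layers(self):
        rng = np.random.default_rng(14)
        v = rng.uniform(0, 1, 8)
        target = amplitude_encode(v / np.linalg.norm(v))
        params, infid, circ = optimize_state_prep(target, layout=(3, 3), tol=1e-3, seed=1)
        assert infid <= 1e-3
        assert circ.n_one_qubit_gates == 18 and circ.n_two_qubit_gates == 9

    def test_convergence_warning_when_underparameterized(self):
        rng = np.random.default_rng(15)
        v = rng.standard_normal(16)
        target = amplitude_encode(v / np.linalg.norm(v))
        with pytest.warns(RuntimeWarning):
            optimize_state_prep(target, layout=(4, 1), tol=1e-12, n_restarts=1)
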