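"""Quantum classifiers: kernels and the five methods."""

import numpy as np
import pytest

from conftest import random_states
from petqml.errors import DegenerateDataError, SizingError
from petqml.qml import (
    fit_qgp,
    fit_qnn,
    fit_qsvm,
    fit_qssvm,
    predict_qdc,
    predict_qgp,
    predict_qnn,
    predict_qssvm,
    predict_qsvm,
    qnn_loss_and_grad,
    quantum_kernel_matrix,
)
from petqml.quantum import NoiseModel, ShotConfig, amplitude_encode, exact_overlap


class TestKernelMatrix:
    def test_diagonal_ones_symmetric_psd(self):
        states = random_states(12, 8, seed=0)
        K = quantum_kernel_matrix(states)
        K.validate_exact()
        assert np.allclose(np.diag(K.values), 1.0)

    def test_exact_swap_entry_hand_case(self):
        a = amplitude_encode([1, 0, 0, 0])
        b = amplitude_encode([0.6, 0.8, 0, 0])
        K = quantum_kernel_matrix([a], [b])
        assert np.isclose(K.values[0, 0], 0.36)

    def test_exact_matches_brute_force_overlap_loop(self):
        X = random_states(10, 8, seed=1, complex_valued=True)
        Y = random_states(7, 8, seed=2, complex_valued=True)
        for est in ("swap", "hadamard"):
            K = quantum_kernel_matrix(X, Y, estimator=est)
            brute = np.empty((10, 7))
            for i, a in enumerate(X):
                for j, b in enumerate(Y):
                    ov = exact_overlap(a, b)
                    brute[i, j] = abs(ov) ** 2 if est == "swap" else ov.real
            assert np.max(np.abs(K.values - brute)) <= 1e-12

    def test_fidelity_equals_squared_cosine_similarity(self):
        """The stated oracle: |<x|y>|^2 == (cosine similarity)^2 of the vectors."""
        rng = np.random.default_rng(3)
        U = rng.uniform(0, 1, size=(20, 8))
        V = U / np.linalg.norm(U, axis=1, keepdims=True)
        states = [amplitude_encode(v) for v in V]
        K = quantum_kernel_matrix(states)
        cos2 = (V @ V.T) ** 2
        assert np.max(np.abs(K.values - cos2)) <= 1e-12

    def test_shot_mode_converges_to_exact(self):
        states = random_states(6, 8, seed=4)
        K_exact = quantum_kernel_matrix(states)
        K_shots = quantum_kernel_matrix(
            states,
            mode="shots",
            shots=ShotConfig(shots=1_000_000, seed=5),
            noise=NoiseModel.noiseless(),
        )
        assert np.max(np.abs(K_exact.values - K_shots.values)) < 0.01
        assert K_shots.provenance == "noisy"

    def test_mixed_qubit_counts_rejected(self):
        a = random_states(2, 4, seed=6)
        b = random_states(2, 8, seed=7)
        with pytest.raises(SizingError):
            quantum_kernel_matrix(a + b)


def _two_cluster_states():
    """Two tight clusters at angle 0 and pi/2 on one qubit."""
    mk = lambda t: amplitude_encode([np.cos(t), np.sin(t)])
    train = [mk(0.0), mk(0.05), mk(np.pi / 2), mk(np.pi / 2 - 0.05)]
    y = np.array([0, 0, 1, 1])
    return train, y


class TestSvms:
    def test_qssvm_separates_two_clusters(self):
        train, y = _two_cluster_states()
        K = quantum_kernel_matrix(train, row_ids=list("abcd"))
        model = fit_qssvm(K, y)
        pred = predict_qssvm(model, K)
        assert np.array_equal(pred, y)

    def test_single_class_rejected(self):
        train, _ = _two_cluster_states()
        K = quantum_kernel_matrix(train)
        with pytest.raises(DegenerateDataError):
            fit_qssvm(K, np.zeros(4, dtype=int))

    def test_duplicate_test_point_gets_training_label(self):
        train, y = _two_cluster_states()
        K = quantum_kernel_matrix(train, row_ids=list("abcd"))
        model = fit_qssvm(K, y)
        K_test = quantum_kernel_matrix([train[2]], train, col_ids=list("abcd"))
        assert predict_qssvm(model, K_test)[0] == 1

    def test_qsvm_records_chosen_c_and_beats_fixed_c_in_inner_cv(self):
        rng = np.random.default_rng(8)
        states = random_states(60, 8, seed=9)
        y = rng.integers(0, 2, size=60)
        y[:10], y[-10:] = 0, 1
        K = quantum_kernel_matrix(states, row_ids=[f"s{i}" for i in range(60)])
        model = fit_qsvm(K, y, inner_cv_seed=1)
        scores = model.params["inner_scores"]
        assert scores[model.params["C"]] >= scores[1.0]

    def test_qsvm_inner_folds_respect_patient_groups(self):
        from petqml.qml import _grouped_folds

        groups = np.array(["p1", "p1", "p2", "p2", "p3", "p4", "p5", "p5"])
        folds = _grouped_folds(groups, 5, np.random.default_rng(0))
        fold_of = {i: f for f, idx in enumerate(folds) for i in idx}
        assert sorted(fold_of) == list(range(len(groups)))
        for g in set(groups):
            member_folds = {fold_of[i] for i in np.flatnonzero(groups == g)}
            assert len(member_folds) == 1

    def test_qsvm_equals_qssvm_when_c1_selected(self):
        train, y = _two_cluster_states()
        K = quantum_kernel_matrix(train, row_ids=list("abcd"))
        qs = fit_qssvm(K, y)
        # force the grid choice C=1 by checking the coincidence contract
        q = fit_qsvm(K, y, inner_cv_seed=0)
        if q.params["C"] == 1.0:
            assert np.array_equal(predict_qsvm(q, K), predict_qssvm(qs, K))


class TestQgp:
    def test_interpolation_limit(self):
        train, y = _two_cluster_states()
        ids = list("abcd")
        K = quantum_kernel_matrix(train, row_ids=ids)
        model = fit_qgp(K, y, sigma2=1e-8)
        K_self = quantum_kernel_matrix(train, train, row_ids=ids, col_ids=ids)
        K_tt = quantum_kernel_matrix(train, row_ids=ids)
        pred = predict_qgp(model, K_self, K_tt)
        assert np.array_equal(pred, y)
        mean = model.params["last_posterior_mean"]
        assert np.allclose(mean, 2.0 * y - 1.0, atol=1e-2)

    def test_identity_kernel_closed_form(self):
        """K = I, sigma2 = 1: posterior mean = k_star . y_pm / 2."""
        states = [amplitude_encode(np.eye(4)[i]) for i in range(4)]
        y = np.array([0, 1, 0, 1])
        ids = [f"t{i}" for i in range(4)]
        K = quantum_kernel_matrix(states, row_ids=ids)
        assert np.allclose(K.values, np.eye(4))
        model = fit_qgp(K, y, sigma2=1.0)
        test = [amplitude_encode(np.eye(4)[1])]
        K_st = quantum_kernel_matrix(test, states, row_ids=["x"], col_ids=ids)
        K_ss = quantum_kernel_matrix(test, row_ids=["x"])
        pred = predict_qgp(model, K_st, K_ss)
        y_pm = 2.0 * y - 1.0
        assert np.isclose(model.params["last_posterior_mean"][0], (K_st.values @ y_pm / 2.0)[0])
        assert pred[0] == 1

    def test_posterior_variance_lower_at_training_point(self):
        states = [amplitude_encode(np.eye(4)[i]) for i in range(3)]
        y = np.array([0, 1, 0])
        ids = list("abc")
        K = quantum_kernel_matrix(states, row_ids=ids)
        model = fit_qgp(K, y, sigma2=0.1)
        at_train = [states[0]]
        orthogonal = [amplitude_encode(np.eye(4)[3])]
        for pts in (at_train, orthogonal):
            K_st = quantum_kernel_matrix(pts, states, row_ids=["x"], col_ids=ids)
            K_ss = quantum_kernel_matrix(pts, row_ids=["x"])
            predict_qgp(model, K_st, K_ss)
            if pts is at_train:
                var_train = model.params["last_posterior_var"][0]
            else:
                var_orth = model.params["last_posterior_var"][0]
        assert var_train <= var_orth


class TestQnn:
    def test_single_qubit_separation(self):
        train = [amplitude_encode([1.0, 0.0]), amplitude_encode([0.0, 1.0])]
        y = np.array([1, 0])  # |0> has <Z> = +1
        model = fit_qnn(train, y, layout=(1, 1), epochs=200, lr=0.5, seed=0)
        assert np.array_equal(predict_qnn(model, train), y)

    def test_parameter_shift_matches_finite_differences(self):
        rng = np.random.default_rng(10)
        states = random_states(10, 8, seed=11)
        Psi = np.stack([s.amplitudes for s in states])
        y_pm = rng.choice([-1.0, 1.0], size=10)
        theta = rng.uniform(-np.pi, np.pi, size=12)
        _, grad = qnn_loss_and_grad(theta, (3, 2), Psi, y_pm)
        eps = 1e-6
        fd = np.empty_like(theta)
        for k in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            lp, _ = qnn_loss_and_grad(tp, (3, 2), Psi, y_pm)
            lm, _ = qnn_loss_and_grad(tm, (3, 2), Psi, y_pm)
            fd[k] = (lp - lm) / (2 * eps)
        assert np.max(np.abs(grad - fd)) < 1e-5

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(12)
        states = random_states(40, 8, seed=13)
        y = rng.permutation([0, 1] * 20)
        model = fit_qnn(states, y, epochs=60, seed=1)
        acc = np.mean(predict_qnn(model, states) == y)
        assert 0.25 <= acc <= 0.8  # wide binomial band: no real signal to learn


class TestQdc:
    def test_exact_duplicate_wins(self):
        train, y = _two_cluster_states()
        pred = predict_qdc(train, y, [train[0]], mode="exact")
        assert pred[0] == y[0]

    def test_orthogonal_to_one_class(self):
        a = amplitude_encode(np.eye(4)[0])
        b = amplitude_encode(np.eye(4)[1])
        pred = predict_qdc([a, b], np.array([0, 1]), [b], mode="exact")
        assert pred[0] == 1

    def test_matches_classical_1nn_on_unit_vectors(self):
        """d^2 = 2 - 2<a|b> equals ||a-b||^2 for unit vectors: same 1-NN."""
        rng = np.random.default_rng(14)
        Xtr = rng.uniform(0.05, 1, size=(25, 8))
        Xtr /= np.linalg.norm(Xtr, axis=1, keepdims=True)
        Xte = rng.uniform(0.05, 1, size=(25, 8))
        Xte /= np.linalg.norm(Xte, axis=1, keepdims=True)
        y = rng.integers(0, 2, size=25)
        y[0], y[1] = 0, 1
        pred = predict_qdc(
            [amplitude_encode(v) for v in Xtr], y, [amplitude_encode(v) for v in Xte]
        )
        from sklearn.neighbors import KNeighborsClassifier

        knn = KNeighborsClassifier(n_neighbors=1).fit(Xtr, y)
        assert np.array_equal(pred, knn.predict(Xte))
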