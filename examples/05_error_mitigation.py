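"""Learned error mitigation on a noisy fidelity kernel.

Builds a noisy shot-sampled kernel, calibrates the random-forest
noisy-to-noiseless regression on training-state pairs, and shows the
kernel-entry error before and after mitigation.
"""

import warnings

import numpy as np

from petqml import build_calibration, fit_em, mitigate_kernel
from petqml.qml import quantum_kernel_matrix
from petqml.quantum import NoiseModel, ShotConfig, amplitude_encode, swap_test_circuit_summary

warnings.filterwarnings("ignore")

rng = np.random.default_rng(0)
V = rng.uniform(0, 1, size=(20, 8))
V /= np.linalg.norm(V, axis=1, keepdims=True)
states = [amplitude_encode(v) for v in V]
ids = [f"s{i}" for i in range(20)]

noise = NoiseModel(p1=0.0005, p2=0.005, readout_eps=0.01)
circ = swap_test_circuit_summary(3)
shots = 16384

K_exact = quantum_kernel_matrix(states, row_ids=ids)
K_noisy = quantum_kernel_matrix(
    states, mode="shots", shots=ShotConfig(shots, seed=1),
    noise=noise, circuit=circ, row_ids=ids,
)
cal = build_calibration(states, 1000, "swap", ShotConfig(shots, seed=2), noise,
                        seed=3, circuit=circ)
em = fit_em(cal, seed=0)
K_mit = mitigate_kernel(K_noisy, em)

off = ~np.eye(20, dtype=bool)
rmse_noisy = np.sqrt(np.mean((K_noisy.values - K_exact.values)[off] ** 2))
rmse_mit = np.sqrt(np.mean((K_mit.values - K_exact.values)[off] ** 2))
print(f"effective depolarizing weight lambda = {noise.effective_lambda(circ):.3f}")
print(f"kernel-entry RMSE vs exact:  noisy {rmse_noisy:.4f}  mitigated {rmse_mit:.4f}")
print(f"mitigated kernel min eigenvalue: {K_mit.min_eigenvalue():.2e} (PSD-repaired)")
# The regression removes the systematic shrinkage; what remains is close
# to the binomial shot floor, and the PSD projection makes the mitigated
# kernel safe for kernel machines.
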