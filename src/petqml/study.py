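"""End-to-end study runners.

The study grid is 3 cohorts x 3 Spearman rank thresholds x 2 feature counts
= 18 dataset variants. For every variant: redundancy-reduce the cohort at
the SRT, reuse the cohort's harmonized ten patient-grouped balanced folds,
select features by R-squared on each fold's training rows, scale and
amplitude-encode, train the five quantum and four classical methods, score
balanced accuracy per fold, and compute the per-fold geometric difference
between the fidelity kernel and an RBF reference kernel on the same
features. The study-level readout is the Pearson correlation between
per-variant GD_Q and dBACC.

The error-mitigation study follows the two-step hardware protocol: first a
single designated fold (first fold, prostate-like cohort, 8 features,
SRT 0.7) compares qsSVM / qGP / qDC across three regimes — noiseless exact,
noisy shot-sampled, and noisy with learned mitigation; then the winning
method is carried across the first fold of all 18 variants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._linalg import rbf_kernel_median_heuristic
from .cml import CML_METHODS, CmlConfig, fit_predict_cml
from .cohorts import FeatureTable, make_three_cohort_suite
from .cv import CVScheme, FoldSplit, make_cv_scheme
from .errors import ConfigurationError
from .evaluate import (
    FoldResult,
    VariantSummary,
    bacc,
    confusion_from_predictions,
    correlate_gd_dbacc,
    gd_score,
    summarize_variant,
)
from .mitigation import build_calibration, fit_em, mitigate_kernel
from .prep import FeatureScaler, r2_rank_select, spearman_redundancy_reduce, zero_pad_normalize
from .qml import (
    fit_qgp,
    fit_qnn,
    fit_qsvm,
    fit_qssvm,
    predict_qdc,
    predict_qgp,
    predict_qnn,
    predict_qssvm,
    predict_qsvm,
    quantum_kernel_matrix,
)
from .quantum import (
    NoiseModel,
    ShotConfig,
    amplitude_encode,
    hadamard_test_circuit_summary,
    swap_test_circuit_summary,
)

__all__ = ["RunConfig", "prepare_fold", "run_variant", "run_full_study", "run_em_study"]

QML_METHODS = ("qsSVM", "qSVM", "qGP", "qNN", "qDC")
COHORT_NAMES = ("prostate", "glioma", "lung")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a study run.

    Defaults reproduce the study grid (3 cohorts x SRT {0.7, 0.8, 0.9} x
    {8, 16} features = 18 variants) on the synthetic cohort suite.
    """

    seed: int = 0
    srt_list: tuple[float, ...] = (0.7, 0.8, 0.9)
    n_select_list: tuple[int, ...] = (8, 16)
    qml_methods: tuple[str, ...] = QML_METHODS
    cml_methods: tuple[str, ...] = CML_METHODS
    shots: int = 2048
    noise: NoiseModel = field(default_factory=NoiseModel)
    em_enabled: bool = True
    n_calibration_pairs: int = 1000
    qnn_epochs: int = 120
    qgp_sigma2: float = 0.1
    output_dir: str | None = None

    def validate(self) -> None:
        for m in self.qml_methods:
            if m not in QML_METHODS:
                raise ConfigurationError(f"unknown QML method {m!r}")
        for m in self.cml_methods:
            if m not in CML_METHODS:
                raise ConfigurationError(f"unknown CML method {m!r}")
        for n in self.n_select_list:
            if n < 2 or (n & (n - 1)) != 0:
                raise ConfigurationError("n_select values must be powers of two > 1")


def n_variants(config: RunConfig, n_cohorts: int = 3) -> int:
    """Size of the study grid."""
    return n_cohorts * len(config.srt_list) * len(config.n_select_list)


@dataclass
class PreparedFold:
    """Everything one fold's methods consume."""

    selected_features: list[str]
    U_train: np.ndarray
    U_test: np.ndarray
    y_train: np.ndarray
    y_test: np.ndarray
    train_ids: list[str]
    test_ids: list[str]
    train_groups: np.ndarray
    train_states: list
    test_states: list
    n_qubits: int


def prepare_fold(
    variant_table: FeatureTable, fold: FoldSplit, n_select: int
) -> PreparedFold:
    """Select, scale, and amplitude-encode one fold of a variant table.

    Feature selection and scaling statistics come from the training rows
    only; test rows are transformed with the train-fitted scaler. Vectors
    are zero-padded to ``n_select`` (a power of two) before encoding.
    """
    train = variant_table.subset(fold.train_ids)
    test = variant_table.subset(fold.test_ids)
    selected = r2_rank_select(train, n_select)
    tr_sel = train.select_features(selected)
    te_sel = test.select_features(selected)
    scaler = FeatureScaler().fit(tr_sel.X)
    U_train = scaler.transform(tr_sel.X)
    U_test = scaler.transform(te_sel.X)
    train_states = [amplitude_encode(zero_pad_normalize(u, n_select)) for u in U_train]
    test_states = [amplitude_encode(zero_pad_normalize(u, n_select)) for u in U_test]
    return PreparedFold(
        selected_features=selected,
        U_train=U_train,
        U_test=U_test,
        y_train=train.labels,
        y_test=test.labels,
        train_ids=list(train.sample_ids),
        test_ids=list(test.sample_ids),
        train_groups=train.patient_ids,
        train_states=train_states,
        test_states=test_states,
        n_qubits=int(np.log2(n_select)),
    )


def _exact_kernels(pf: PreparedFold):
    K_tr = quantum_kernel_matrix(pf.train_states, row_ids=pf.train_ids, estimator="swap")
    K_te_tr = quantum_kernel_matrix(
        pf.test_states, pf.train_states, estimator="swap",
        row_ids=pf.test_ids, col_ids=pf.train_ids,
    )
    K_te_te = quantum_kernel_matrix(pf.test_states, row_ids=pf.test_ids, estimator="swap")
    return K_tr, K_te_tr, K_te_te


def run_fold_methods(
    pf: PreparedFold,
    config: RunConfig,
    fold_seed: int,
) -> dict[str, np.ndarray]:
    """Run the configured methods on one prepared fold; returns predictions."""
    preds: dict[str, np.ndarray] = {}
    need_kernels = any(m in config.qml_methods for m in ("qsSVM", "qSVM", "qGP"))
    if need_kernels:
        K_tr, K_te_tr, K_te_te = _exact_kernels(pf)
    if "qsSVM" in config.qml_methods:
        preds["qsSVM"] = predict_qssvm(fit_qssvm(K_tr, pf.y_train), K_te_tr)
    if "qSVM" in config.qml_methods:
        state = fit_qsvm(K_tr, pf.y_train, inner_cv_seed=fold_seed, groups=pf.train_groups)
        preds["qSVM"] = predict_qsvm(state, K_te_tr)
    if "qGP" in config.qml_methods:
        state = fit_qgp(K_tr, pf.y_train, sigma2=config.qgp_sigma2)
        preds["qGP"] = predict_qgp(state, K_te_tr, K_te_te)
    if "qNN" in config.qml_methods:
        state = fit_qnn(
            pf.train_states, pf.y_train, epochs=config.qnn_epochs, seed=fold_seed
        )
        preds["qNN"] = predict_qnn(state, pf.test_states)
    if "qDC" in config.qml_methods:
        preds["qDC"] = predict_qdc(pf.train_states, pf.y_train, pf.test_states, mode="exact")
    for m in config.cml_methods:
        cfg = CmlConfig(method=m, seed=fold_seed)
        preds[m] = fit_predict_cml(cfg, pf.U_train, pf.y_train, pf.U_test)
    return preds


def run_variant(
    variant_table: FeatureTable,
    scheme: CVScheme,
    config: RunConfig,
    cohort: str,
    srt: float,
    n_select: int,
) -> VariantSummary:
    """Run all folds of one dataset variant and aggregate."""
    fold_results: list[FoldResult] = []
    gd_per_fold: list[float] = []
    for fold in scheme.folds:
        pf = prepare_fold(variant_table, fold, n_select)
        fold_seed = (config.seed * 1009 + fold.fold_id * 101) % (2**31 - 1)
        preds = run_fold_methods(pf, config, fold_seed)
        for method, y_pred in preds.items():
            counts = confusion_from_predictions(pf.y_test, y_pred)
            fold_results.append(
                FoldResult(
                    cohort=cohort, srt=srt, n_select=n_select,
                    fold_id=fold.fold_id, method=method,
                    counts=counts, bacc=bacc(counts),
                )
            )
        K_C, _ = rbf_kernel_median_heuristic(pf.U_train)
        K_Q = quantum_kernel_matrix(pf.train_states, estimator="swap")
        gd_per_fold.append(gd_score(K_C, K_Q))
    return summarize_variant(fold_results, gd_per_fold, n_folds=len(scheme.folds))


def run_full_study(
    config: RunConfig, cohorts: list[tuple[str, FeatureTable]] | None = None
) -> dict:
    """Execute the full grid: prep -> CV -> QML/CML -> GD_Q -> summaries.

    ``cohorts`` defaults to the synthetic three-cohort suite. Returns a
    dict with the per-variant summaries, the GD_Q-vs-dBACC correlation, and
    (when ``config.output_dir`` is set) writes the tabular outputs.
    """
    config.validate()
    if cohorts is None:
        cohorts = list(zip(COHORT_NAMES, make_three_cohort_suite(config.seed)))

    summaries: list[VariantSummary] = []
    for c_idx, (name, table) in enumerate(cohorts):
        scheme = make_cv_scheme(table, seed=config.seed + 17 * c_idx, cohort_id=name)
        for srt in config.srt_list:
            reduced, _report = spearman_redundancy_reduce(table, srt)
            for n_select in config.n_select_list:
                summaries.append(
                    run_variant(reduced, scheme, config, name, srt, n_select)
                )

    try:
        corr = correlate_gd_dbacc(summaries)
    except Exception:
        corr = None
    results = {"summaries": summaries, "correlation": corr, "config": config}
    if config.output_dir:
        _write_outputs(results, Path(config.output_dir))
    return results


def summaries_frame(summaries: list[VariantSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for m, mu in s.method_mean.items():
            rows.append(
                {
                    "cohort": s.cohort, "srt": s.srt, "n_select": s.n_select,
                    "method": m, "mean_bacc": mu, "ci95": s.method_ci[m],
                    "qbacc": s.qbacc, "cbacc": s.cbacc, "dbacc": s.dbacc,
                    "gd_q": s.gd_q,
                }
            )
    return pd.DataFrame(rows)


def _write_outputs(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    summaries_frame(results["summaries"]).to_csv(outdir / "variant_summaries.csv", index=False)
    corr = results["correlation"]
    if corr is not None:
        (outdir / "gd_dbacc_correlation.json").write_text(
            json.dumps({"r": corr.r, "p": corr.p, "n": corr.n}, indent=1)
        )


# --------------------------------------------------------------------------
# error-mitigation study
# --------------------------------------------------------------------------

EM_STEP1_METHODS = ("qsSVM", "qGP", "qDC")
EM_WINNER_TIEBREAK = ("qsSVM", "qDC", "qGP")


def _noisy_and_mitigated_predictions(
    pf: PreparedFold, config: RunConfig, seed: int, methods: tuple[str, ...]
) -> dict[str, dict[str, float]]:
    """BACC of each method under exact / noisy / mitigated kernel regimes."""
    noise = config.noise
    swap_circ = swap_test_circuit_summary(pf.n_qubits)
    had_circ = hadamard_test_circuit_summary(pf.n_qubits)
    out: dict[str, dict[str, float]] = {m: {} for m in methods}

    # exact regime
    K_tr, K_te_tr, K_te_te = _exact_kernels(pf)
    K_te_tr_h = quantum_kernel_matrix(
        pf.test_states, pf.train_states, estimator="hadamard",
        row_ids=pf.test_ids, col_ids=pf.train_ids,
    )

    # noisy regime: every kernel block re-estimated through the shot pipeline
    def noisy_block(X, Y, estimator, circ, s):
        rids = pf.train_ids if X is pf.train_states else pf.test_ids
        cids = rids if Y is None else pf.train_ids
        return quantum_kernel_matrix(
            X, Y, mode="shots", estimator=estimator,
            shots=ShotConfig(shots=config.shots, seed=s),
            noise=noise, circuit=circ,
            row_ids=rids, col_ids=cids,
        )

    Kn_tr = noisy_block(pf.train_states, None, "swap", swap_circ, seed + 1)
    Kn_te_tr = noisy_block(pf.test_states, pf.train_states, "swap", swap_circ, seed + 2)
    Kn_te_te = noisy_block(pf.test_states, None, "swap", swap_circ, seed + 3)
    Kn_te_tr_h = noisy_block(pf.test_states, pf.train_states, "hadamard", had_circ, seed + 4)

    # mitigation models, calibrated on training states only
    shots_cfg = ShotConfig(shots=config.shots, seed=seed + 5)
    em_swap = fit_em(
        build_calibration(
            pf.train_states, config.n_calibration_pairs, "swap",
            shots_cfg, noise, seed=seed + 6, circuit=swap_circ,
        ),
        seed=seed + 7,
    )
    em_had = fit_em(
        build_calibration(
            pf.train_states, config.n_calibration_pairs, "hadamard",
            shots_cfg, noise, seed=seed + 8, circuit=had_circ,
        ),
        seed=seed + 9,
    )
    Km_tr = mitigate_kernel(Kn_tr, em_swap)
    Km_te_tr = mitigate_kernel(Kn_te_tr, em_swap)
    Km_te_te = mitigate_kernel(Kn_te_te, em_swap)
    Km_te_tr_h = mitigate_kernel(Kn_te_tr_h, em_had)

    regimes = {
        "simulator": (K_tr, K_te_tr, K_te_te, K_te_tr_h),
        "no_em": (Kn_tr, Kn_te_tr, Kn_te_te, Kn_te_tr_h),
        "with_em": (Km_tr, Km_te_tr, Km_te_te, Km_te_tr_h),
    }
    for regime, (A, B, C, H) in regimes.items():
        for m in methods:
            if m == "qsSVM":
                pred = predict_qssvm(fit_qssvm(A, pf.y_train), B)
            elif m == "qGP":
                pred = predict_qgp(fit_qgp(A, pf.y_train, config.qgp_sigma2), B, C)
            elif m == "qDC":
                pred = predict_qdc(
                    pf.train_states, pf.y_train, pf.test_states, K_test_train=H
                )
            else:
                raise ConfigurationError(f"method {m!r} not in the EM study")
            out[m][regime] = bacc(confusion_from_predictions(pf.y_test, pred))
    return out


def run_em_study(
    config: RunConfig, cohorts: list[tuple[str, FeatureTable]] | None = None
) -> dict:
    """Two-step error-mitigation evaluation on the first fold of each variant.

    Step 1 compares qsSVM / qGP / qDC in the three regimes on the
    designated fold (prostate-like cohort, SRT 0.7, 8 features, first
    fold). Step 2 carries the winner — highest BACC considering both the
    noisy and mitigated regimes, ties broken qsSVM > qDC > qGP — across the
    first fold of all 18 variants and reports the three-regime average.
    """
    config.validate()
    if cohorts is None:
        cohorts = list(zip(COHORT_NAMES, make_three_cohort_suite(config.seed)))
    name_to_table = dict(cohorts)

    # step 1: designated fold
    prostate = name_to_table[cohorts[0][0]]
    scheme_p = make_cv_scheme(prostate, seed=config.seed, cohort_id=cohorts[0][0])
    reduced_p, _ = spearman_redundancy_reduce(prostate, 0.7)
    pf = prepare_fold(reduced_p, scheme_p.folds[0], 8)
    step1 = _noisy_and_mitigated_predictions(
        pf, config, seed=config.seed * 977 % (2**31 - 1), methods=EM_STEP1_METHODS
    )

    def winner_key(m: str) -> tuple:
        best = max(step1[m]["no_em"], step1[m]["with_em"])
        return (best, -EM_WINNER_TIEBREAK.index(m))

    winner = max(EM_STEP1_METHODS, key=winner_key)

    # step 2: winner across the first fold of all variants
    step2_rows = []
    for c_idx, (name, table) in enumerate(cohorts):
        scheme = make_cv_scheme(table, seed=config.seed + 17 * c_idx, cohort_id=name)
        for srt in config.srt_list:
            reduced, _ = spearman_redundancy_reduce(table, srt)
            for n_select in config.n_select_list:
                pfv = prepare_fold(reduced, scheme.folds[0], n_select)
                seed_v = (
                    config.seed * 7919 + c_idx * 131 + int(srt * 10) * 17 + n_select
                ) % (2**31 - 1)
                res = _noisy_and_mitigated_predictions(
                    pfv, config, seed=seed_v, methods=(winner,)
                )[winner]
                step2_rows.append(
                    {
                        "cohort": name, "srt": srt, "n_select": n_select,
                        "simulator": res["simulator"], "no_em": res["no_em"],
                        "with_em": res["with_em"],
                    }
                )
    step2 = pd.DataFrame(step2_rows)
    averages = {
        "simulator": float(step2["simulator"].mean()),
        "no_em": float(step2["no_em"].mean()),
        "with_em": float(step2["with_em"].mean()),
    }
    results = {
        "step1": step1,
        "winner": winner,
        "step2": step2,
        "averages": averages,
        "config": config,
    }
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(step1).T.to_csv(outdir / "em_step1.csv")
        avg_row = {"cohort": "average", "srt": "", "n_select": "", **averages}
        pd.concat([step2, pd.DataFrame([avg_row])]).to_csv(
            outdir / "em_step2.csv", index=False
        )
    return results
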