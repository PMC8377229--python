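"""Simulation-based validation experiments for the estimator suite.

These experiments define the package's statistical guarantees on
synthetic data at the scale of the real study (exposure GWAS n≈321k,
binary-outcome GWAS n≈1.03M at ~5.9% case fraction, per-allele exposure
effects of genome-wide-significant birth-weight loci):

* parameter recovery and CI coverage of IVW under no pleiotropy;
* type-I error of IVW and of the Egger intercept test under balanced
  pleiotropy;
* robustness of the weighted median against 30% invalid instruments
  with directional pleiotropy;
* MR-PRESSO outlier detection power (planted k-SE outlier) and null
  calibration of its global p-value.

Every replicate draws a fresh study (MAFs, hence SEs, and true effects),
so reported rates average over study configurations rather than
conditioning on one. Each experiment takes an explicit seed and is
deterministic given it.
"""

from __future__ import annotations

import numpy as np

from .diagnostics import mr_presso
from .estimators import ivw, median_estimator, mr_egger
from .summary_data import HarmonizedInstrument

__all__ = [
    "study_scale_ses",
    "instruments_from_arrays",
    "ivw_recovery",
    "type_i_error",
    "median_robustness",
    "presso_outlier_flag_rate",
    "presso_null_pvalues",
]

N_EXPOSURE = 321_223
N_OUTCOME = 1_030_836
CASE_FRACTION = 60_620 / 1_030_836
GAMMA_RANGE = (0.015, 0.06)


def study_scale_ses(rng: np.random.Generator, n_snps: int):
    """Per-SNP exposure/outcome SEs at the real GWASs' sample sizes."""
    maf = rng.uniform(0.1, 0.5, n_snps)
    sx = 1.0 / np.sqrt(2 * maf * (1 - maf) * N_EXPOSURE)
    sy = 1.0 / np.sqrt(
        2 * maf * (1 - maf) * N_OUTCOME * CASE_FRACTION * (1 - CASE_FRACTION)
    )
    return sx, sy


def instruments_from_arrays(bx, sx, by, sy) -> list[HarmonizedInstrument]:
    return [
        HarmonizedInstrument(
            rsid=f"rs{i}",
            effect_allele="A",
            beta_exposure=float(bx[i]),
            se_exposure=float(sx[i]),
            beta_outcome=float(by[i]),
            se_outcome=float(sy[i]),
        )
        for i in range(len(bx))
    ]


def ivw_recovery(
    seed: int,
    n_reps: int = 1000,
    n_snps: int = 144,
    true_beta: float = 0.233,
) -> dict:
    """IVW bias and 95% CI coverage under the no-pleiotropy model."""
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_reps)
    covered = 0
    for r in range(n_reps):
        sx, sy = study_scale_ses(rng, n_snps)
        gamma = rng.uniform(*GAMMA_RANGE, n_snps) * rng.choice([-1.0, 1.0], n_snps)
        bx = gamma + rng.normal(0, sx)
        by = true_beta * gamma + rng.normal(0, sy)
        est = ivw(instruments_from_arrays(bx, sx, by, sy))
        estimates[r] = est.beta
        covered += est.ci_low <= true_beta <= est.ci_high
    return {
        "mean_bias": float(estimates.mean() - true_beta),
        "coverage": covered / n_reps,
        "n_reps": n_reps,
        "n_snps": n_snps,
        "true_beta": true_beta,
    }


def type_i_error(
    seed: int,
    n_reps: int = 1000,
    n_snps: int = 144,
    pleiotropy_sd: float = 0.005,
) -> dict:
    """Null rejection rates of IVW (β=0) and the Egger intercept test
    under balanced pleiotropy of the stated SD."""
    rng = np.random.default_rng(seed)
    rej_ivw = rej_egger = 0
    for _ in range(n_reps):
        sx, sy = study_scale_ses(rng, n_snps)
        gamma = rng.uniform(*GAMMA_RANGE, n_snps) * rng.choice([-1.0, 1.0], n_snps)
        alpha = rng.normal(0.0, pleiotropy_sd, n_snps)
        bx = gamma + rng.normal(0, sx)
        by = alpha + rng.normal(0, sy)
        insts = instruments_from_arrays(bx, sx, by, sy)
        rej_ivw += ivw(insts).pvalue < 0.05
        rej_egger += mr_egger(insts).intercept_pvalue < 0.05
    return {
        "ivw_rate": rej_ivw / n_reps,
        "egger_intercept_rate": rej_egger / n_reps,
        "n_reps": n_reps,
        "n_snps": n_snps,
    }


def median_robustness(
    seed: int,
    n_reps: int = 200,
    n_snps: int = 50,
    true_beta: float = 0.25,
    invalid_fraction: float = 0.3,
    invalid_mean: float = 0.05,
    n_boot: int = 50,
) -> dict:
    """Bias of IVW vs the weighted median with an invalid-instrument
    minority carrying directional pleiotropy. Exposure effects are
    oriented positive, the convention under which directional pleiotropy
    accumulates rather than cancels."""
    rng = np.random.default_rng(seed)
    n_invalid = int(round(invalid_fraction * n_snps))
    ivw_est = np.empty(n_reps)
    med_est = np.empty(n_reps)
    for r in range(n_reps):
        sx, sy = study_scale_ses(rng, n_snps)
        gamma = rng.uniform(*GAMMA_RANGE, n_snps)
        alpha = np.zeros(n_snps)
        alpha[rng.choice(n_snps, n_invalid, replace=False)] = rng.normal(
            invalid_mean, 0.01, n_invalid
        )
        bx = gamma + rng.normal(0, sx)
        by = true_beta * gamma + alpha + rng.normal(0, sy)
        insts = instruments_from_arrays(bx, sx, by, sy)
        ivw_est[r] = ivw(insts).beta
        med_est[r] = median_estimator(
            insts, weighted=True, n_boot=n_boot, seed=int(rng.integers(2**31))
        ).beta
    return {
        "ivw_abs_bias": float(abs(ivw_est.mean() - true_beta)),
        "weighted_median_abs_bias": float(abs(med_est.mean() - true_beta)),
        "n_reps": n_reps,
        "n_snps": n_snps,
    }


def presso_outlier_flag_rate(
    seed: int,
    n_runs: int = 100,
    n_snps: int = 50,
    shift_se: float = 5.0,
    n_sim: int = 2000,
    true_beta: float = 0.25,
) -> float:
    """Fraction of runs in which a single SNP with its outcome effect
    shifted by ``shift_se`` outcome-SEs is flagged as an outlier."""
    rng = np.random.default_rng(seed)
    flagged = 0
    for _ in range(n_runs):
        sx, sy = study_scale_ses(rng, n_snps)
        gamma = rng.uniform(*GAMMA_RANGE, n_snps) * rng.choice([-1.0, 1.0], n_snps)
        bx = gamma + rng.normal(0, sx)
        by = true_beta * gamma + rng.normal(0, sy)
        by[0] += shift_se * sy[0]
        res = mr_presso(
            instruments_from_arrays(bx, sx, by, sy),
            n_sim=n_sim,
            seed=int(rng.integers(2**31)),
        )
        flagged += "rs0" in res.outliers
    return flagged / n_runs


def presso_null_pvalues(
    seed: int,
    n_runs: int = 200,
    n_snps: int = 50,
    n_sim: int = 300,
    true_beta: float = 0.25,
) -> np.ndarray:
    """MR-PRESSO global p-values over clean-null replicates; should be
    approximately uniform on (0, 1)."""
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_runs)
    for r in range(n_runs):
        sx, sy = study_scale_ses(rng, n_snps)
        gamma = rng.uniform(*GAMMA_RANGE, n_snps) * rng.choice([-1.0, 1.0], n_snps)
        bx = gamma + rng.normal(0, sx)
        by = true_beta * gamma + rng.normal(0, sy)
        pvals[r] = mr_presso(
            instruments_from_arrays(bx, sx, by, sy),
            n_sim=n_sim,
            seed=int(rng.integers(2**31)),
        ).global_p
    return pvals
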