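"""Pleiotropy and influence diagnostics.

Horizontal pleiotropy — a SNP affecting the outcome through a path other
than the exposure — is the main threat to MR validity. This module
implements the standard diagnostic battery: the MR-Egger intercept test
for directional pleiotropy, leave-one-out influence analysis, funnel
asymmetry data, Cochran's Q heterogeneity statistic, and MR-PRESSO
(residual-sum-of-squares global test, per-SNP outlier test, and a
distortion test for the outlier-corrected estimate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EstimatorError, MrEstimate, _arrays, _ivw_core, ivw, mr_egger
from .summary_data import HarmonizedInstrument

__all__ = [
    "EggerInterceptTest",
    "LeaveOneOutResult",
    "PressoResult",
    "egger_intercept_test",
    "leave_one_out",
    "funnel_data",
    "cochran_q",
    "mr_presso",
]


@dataclass(frozen=True)
class EggerInterceptTest:
    """The intercept block of MR-Egger, with the paper-rule verdict."""

    intercept: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    #: True iff p > 0.05 — no evidence of directional pleiotropy
    no_directional_pleiotropy: bool


@dataclass(frozen=True)
class LeaveOneOutResult:
    full: MrEstimate
    estimates: dict[str, MrEstimate]
    #: rsids whose omission moves the estimate outside the full-set 95% CI
    flagged: list[str]


@dataclass(frozen=True)
class QResult:
    q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class PressoResult:
    global_rss: float
    global_p: float
    outlier_p: dict[str, float]
    outliers: list[str]
    corrected: MrEstimate
    distortion_p: Optional[float]


def egger_intercept_test(instruments: Sequence[HarmonizedInstrument]) -> EggerInterceptTest:
    """Directional-pleiotropy test from the MR-Egger intercept.

    A nonzero intercept means the average pleiotropic effect is not
    zero; the conventional rule declares no directional pleiotropy when
    the intercept p-value exceeds 0.05.
    """
    egger = mr_egger(instruments)
    return EggerInterceptTest(
        intercept=egger.intercept,
        se=egger.intercept_se,
        ci_low=egger.intercept_ci_low,
        ci_high=egger.intercept_ci_high,
        pvalue=egger.intercept_pvalue,
        no_directional_pleiotropy=egger.intercept_pvalue > 0.05,
    )


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    ivw_model: str = "auto",
) -> LeaveOneOutResult:
    """Re-estimate (IVW) J times, each omitting one SNP.

    A SNP is flagged as disproportionately influential when the estimate
    without it falls outside the full-set 95% CI.
    """
    J = len(instruments)
    if J < 2:
        raise EstimatorError("leave-one-out needs at least 2 instruments")
    full = ivw(instruments, model=ivw_model)
    estimates: dict[str, MrEstimate] = {}
    flagged: list[str] = []
    for j, inst in enumerate(instruments):
        rest = list(instruments[:j]) + list(instruments[j + 1:])
        est = ivw(rest, model=ivw_model)
        estimates[inst.rsid] = est
        if not (full.ci_low <= est.beta <= full.ci_high):
            flagged.append(inst.rsid)
    return LeaveOneOutResult(full=full, estimates=estimates, flagged=flagged)


def funnel_data(instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Funnel-plot data: per SNP the Wald ratio and its precision
    (inverse first-order SE), plus the overall IVW position.

    Under balanced pleiotropy the scatter is symmetric about the IVW
    line; asymmetry suggests directional pleiotropy.
    """
    bx, sx, by, sy = _arrays(instruments)
    ratio = by / bx
    precision = np.abs(bx) / sy
    df = pd.DataFrame(
        {
            "rsid": [i.rsid for i in instruments],
            "ratio": ratio,
            "precision": precision,
        }
    )
    df.attrs["ivw_beta"] = ivw(instruments).beta if len(instruments) > 0 else float("nan")
    return df


def cochran_q(instruments: Sequence[HarmonizedInstrument]) -> QResult:
    """Cochran's Q heterogeneity statistic over the Wald ratios,
    Q = Σ w_j (β_j − β_IVW)², referred to χ²(J−1)."""
    J = len(instruments)
    if J < 2:
        raise EstimatorError("Cochran's Q needs at least 2 instruments")
    bx, sx, by, sy = _arrays(instruments)
    _, _, q = _ivw_core(bx, sx, by, sy, "fixed")
    return QResult(q=q, df=J - 1, pvalue=float(stats.chi2.sf(q, J - 1)))


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW (origin-WLS) slopes for every SNP, O(J)."""
    sxy = (w * bx * by).sum()
    sxx = (w * bx * bx).sum()
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    outlier_threshold: float = 0.05,
    seed: Optional[int] = None,
    ivw_model: str = "auto",
) -> PressoResult:
    """MR-PRESSO: pleiotropy residual sum and outlier test.

    Global test: the observed RSS sums each SNP's weighted squared
    residual about its leave-one-out IVW prediction; the null
    distribution comes from ``n_sim`` parametric simulations drawing
    γ*_j ~ N(γ_j, σ_xj) and Γ*_j ~ N(β₋ⱼγ_j, σ_yj) and recomputing the
    RSS the same way. Outlier test: per-SNP p is the fraction of that
    SNP's simulated squared residuals at or above its observed one,
    Bonferroni-adjusted across J. Distortion test: the shift between the
    full and outlier-corrected IVW estimates is referred to a null built
    by removing equally many SNPs at random. Empirical p-values use the
    (r+1)/(n+1) estimator.
    """
    J = len(instruments)
    if J < 4:
        raise EstimatorError("MR-PRESSO needs at least 4 instruments")
    if n_sim < 100:
        raise EstimatorError("MR-PRESSO needs n_sim >= 100")
    if seed is None:
        raise EstimatorError("MR-PRESSO requires an explicit seed")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = _arrays(instruments)
    w = sy**-2.0

    beta_loo = _loo_slopes(bx, by, w)
    obs_sq = w * (by - beta_loo * bx) ** 2
    global_rss = float(obs_sq.sum())

    # parametric null: data regenerated about the leave-one-out fits
    bx_sim = rng.normal(bx, sx, size=(n_sim, J))
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, J))
    sxy = (w * bx_sim * by_sim).sum(axis=1, keepdims=True)
    sxx = (w * bx_sim * bx_sim).sum(axis=1, keepdims=True)
    loo_sim = (sxy - w * bx_sim * by_sim) / (sxx - w * bx_sim * bx_sim)
    sim_sq = w * (by_sim - loo_sim * bx_sim) ** 2
    sim_rss = sim_sq.sum(axis=1)
    global_p = float((np.sum(sim_rss >= global_rss) + 1) / (n_sim + 1))

    outlier_p: dict[str, float] = {}
    outliers: list[str] = []
    for j, inst in enumerate(instruments):
        p_raw = float((np.sum(sim_sq[:, j] >= obs_sq[j]) + 1) / (n_sim + 1))
        p_adj = min(1.0, p_raw * J)
        outlier_p[inst.rsid] = p_adj
        if p_adj < outlier_threshold:
            outliers.append(inst.rsid)

    keep = [inst for inst in instruments if inst.rsid not in outliers]
    if len(keep) == 0:
        raise EstimatorError("MR-PRESSO flagged every instrument as an outlier")
    corrected = ivw(keep, model=ivw_model)

    distortion_p: Optional[float] = None
    if outliers:
        full = ivw(list(instruments), model=ivw_model)
        obs_shift = abs(corrected.beta - full.beta)
        k = len(outliers)
        shifts = np.empty(n_sim)
        idx = np.arange(J)
        for b in range(n_sim):
            drop = rng.choice(idx, size=k, replace=False)
            mask = np.ones(J, dtype=bool)
            mask[drop] = False
            bsub, _, _ = _ivw_core(bx[mask], sx[mask], by[mask], sy[mask], ivw_model)
            shifts[b] = abs(bsub - full.beta)
        distortion_p = float((np.sum(shifts >= obs_shift) + 1) / (n_sim + 1))

    return PressoResult(
        global_rss=global_rss,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=outliers,
        corrected=corrected,
        distortion_p=distortion_p,
    )
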