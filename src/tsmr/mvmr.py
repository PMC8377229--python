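"""Multivariable MR and mediation decomposition.

Regressing the outcome associations jointly on the exposure and
mediator associations (weights σ_y⁻², no intercept) yields the direct
effect of the exposure conditional on the mediator. With the
univariable (total) effect in hand, the difference method decomposes

    indirect = total − direct,    proportion mediated = indirect/total,

and each log-odds effect converts to a percent risk change as
(exp(β) − 1) × 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import EstimatorError, MrEstimate
from .summary_data import HarmonizedInstrument

__all__ = [
    "MvmrEstimate",
    "MediationResult",
    "mvmr_ivw",
    "mediation_decompose",
    "beta_to_percent",
    "percent_to_beta",
    "mvmr_to_frame",
]


@dataclass(frozen=True)
class MvmrEstimate:
    """Per-exposure conditional estimates from one multivariable fit."""

    exposure: MrEstimate  # exposure effect conditional on the mediator
    mediator: MrEstimate  # mediator effect conditional on the exposure
    n_snps: int
    conditioning: tuple[str, str] = ("exposure", "mediator")


@dataclass(frozen=True)
class MediationResult:
    """Difference-method decomposition of a total effect."""

    total_beta: float
    direct_beta: float
    indirect_beta: float
    proportion_mediated: Optional[float]
    percent_total: tuple[float, float, float]  # point, ci_low, ci_high
    percent_direct: tuple[float, float, float]


def mvmr_ivw(
    instruments: Sequence[HarmonizedInstrument],
    ivw_model: str = "auto",
    labels: tuple[str, str] = ("exposure | mediator", "mediator | exposure"),
) -> MvmrEstimate:
    """Multivariable IVW: weighted regression of Γ on (γ_exposure,
    γ_mediator) with no intercept and weights σ_y⁻².

    Per-coefficient SEs carry the same multiplicative overdispersion
    scaling as univariable IVW (√max(1, RSS/(J−k)) when the model is
    random/auto).
    """
    insts = [i for i in instruments if i.beta_mediator is not None]
    J = len(insts)
    if J < 3:
        raise EstimatorError("multivariable IVW needs >= 3 instruments with mediator effects")
    bx = np.array([i.beta_exposure for i in insts])
    bm = np.array([i.beta_mediator for i in insts])
    by = np.array([i.beta_outcome for i in insts])
    sy = np.array([i.se_outcome for i in insts])
    X = np.column_stack([bx, bm])
    w = sy**-2.0
    XtW = X.T * w
    xtwx = XtW @ X
    if np.linalg.cond(xtwx) > 1e12:
        raise EstimatorError("exposure and mediator effect columns are collinear")
    coef = np.linalg.solve(xtwx, XtW @ by)
    resid = by - X @ coef
    rss = float((w * resid**2).sum())
    k = 2
    if ivw_model == "fixed" or (ivw_model == "auto" and J <= 3):
        phi = 1.0
    else:
        phi = max(1.0, rss / (J - k))
    cov = np.linalg.inv(xtwx) * phi
    ses = np.sqrt(np.diag(cov))
    return MvmrEstimate(
        exposure=MrEstimate.from_beta_se(labels[0], float(coef[0]), float(ses[0]), J),
        mediator=MrEstimate.from_beta_se(labels[1], float(coef[1]), float(ses[1]), J),
        n_snps=J,
        conditioning=labels,
    )


def beta_to_percent(beta: float, ci_low: Optional[float] = None, ci_high: Optional[float] = None):
    """Percent risk change (exp(β) − 1) × 100, applied to point and CI."""
    pct = (math.exp(beta) - 1.0) * 100.0
    if ci_low is None or ci_high is None:
        return pct
    return pct, (math.exp(ci_low) - 1.0) * 100.0, (math.exp(ci_high) - 1.0) * 100.0


def percent_to_beta(percent: float) -> float:
    return math.log(1.0 + percent / 100.0)


def mediation_decompose(total: MrEstimate, direct: MrEstimate) -> MediationResult:
    """Difference-method mediation: indirect = total − direct.

    Both estimates must be on the same log-odds scale. The proportion
    mediated is undefined (None) when the total effect is exactly zero.
    """
    indirect = total.beta - direct.beta
    proportion = None if total.beta == 0 else indirect / total.beta
    return MediationResult(
        total_beta=total.beta,
        direct_beta=direct.beta,
        indirect_beta=indirect,
        proportion_mediated=proportion,
        percent_total=beta_to_percent(total.beta, total.ci_low, total.ci_high),
        percent_direct=beta_to_percent(direct.beta, direct.ci_low, direct.ci_high),
    )


def mvmr_to_frame(est: MvmrEstimate, exposure_label: str, mediator_label: str, outcome_label: str) -> pd.DataFrame:
    """Serialize a multivariable fit to a two-row conditional-effects table."""
    rows = []
    for lab, e in ((exposure_label, est.exposure), (mediator_label, est.mediator)):
        rows.append(
            {
                "exposure": lab,
                "outcome": outcome_label,
                "n_snps": est.n_snps,
                "beta": e.beta,
                "se": e.se,
                "or": e.or_value,
                "or_low": e.or_low,
                "or_high": e.or_high,
                "pvalue": e.pvalue,
            }
        )
    return pd.DataFrame(rows)
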