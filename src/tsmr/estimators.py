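"""Causal-effect estimators for two-sample MR.

Each instrument j contributes an exposure association γ_j (SE σ_xj) and
an outcome association Γ_j (SE σ_yj). Under the instrumental-variable
assumptions, Γ_j = β γ_j for the causal effect β, so each SNP yields a
Wald ratio Γ_j/γ_j and the estimators differ in how they pool the
ratios and which invalid-instrument patterns they tolerate:

* IVW — inverse-variance-weighted mean of the ratios (equivalently WLS
  of Γ on γ through the origin); efficient but biased by any directional
  pleiotropy. The primary method.
* maximum likelihood — joint normal likelihood over the true γ_j and β;
  accounts for exposure-side measurement error.
* simple/weighted median — consistent when ≥ 50% of the weight comes
  from valid instruments.
* simple/weighted mode — consistent when the largest group of
  instruments shares the same true ratio (ZEMPA).
* MR-Egger — WLS of Γ on γ with a free intercept; the slope is
  consistent under InSIDE even with directional pleiotropy, and the
  intercept estimates the average pleiotropic effect.

Binary-outcome effects are on the log-odds scale, so every estimate is
also reported as an odds ratio per SD of exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .summary_data import HarmonizedInstrument

__all__ = [
    "MrEstimate",
    "EggerEstimate",
    "EstimatorError",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "median_estimator",
    "mode_estimator",
    "max_likelihood",
    "estimate_all",
    "estimates_to_frame",
]

_Z975 = stats.norm.ppf(0.975)


class EstimatorError(ValueError):
    """An estimator's preconditions are not met."""


@dataclass(frozen=True)
class MrEstimate:
    """A method-labeled causal estimate on the log-odds (beta) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int

    @property
    def or_value(self) -> float:
        return math.exp(self.beta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)

    @classmethod
    def from_beta_se(
        cls,
        method: str,
        beta: float,
        se: float,
        n_snps: int,
        df: Optional[int] = None,
    ) -> "MrEstimate":
        """Wald-type estimate; normal reference by default, t(df) when given."""
        if df is not None:
            crit = stats.t.ppf(0.975, df)
            p = 2 * stats.t.sf(abs(beta / se), df) if se > 0 else (1.0 if beta == 0 else 0.0)
        else:
            crit = _Z975
            p = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
        return cls(
            method=method,
            beta=beta,
            se=se,
            ci_low=beta - crit * se,
            ci_high=beta + crit * se,
            pvalue=float(p),
            n_snps=n_snps,
        )


@dataclass(frozen=True)
class EggerEstimate:
    """MR-Egger slope plus the pleiotropy intercept block."""

    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_ci_low: float
    intercept_ci_high: float
    intercept_pvalue: float


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    bx = np.array([i.beta_exposure for i in instruments], dtype=float)
    sx = np.array([i.se_exposure for i in instruments], dtype=float)
    by = np.array([i.beta_outcome for i in instruments], dtype=float)
    sy = np.array([i.se_outcome for i in instruments], dtype=float)
    return bx, sx, by, sy


def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False) -> MrEstimate:
    """Single-SNP causal estimate Γ/γ with delta-method SE.

    First-order SE is σ_y/|γ|; the second-order form adds the
    exposure-side term Γ²σ_x²/γ⁴ under the square root.
    """
    if inst.beta_exposure == 0:
        raise EstimatorError(f"{inst.rsid}: zero exposure beta, Wald ratio undefined")
    g, sx = inst.beta_exposure, inst.se_exposure
    G, sy = inst.beta_outcome, inst.se_outcome
    beta = G / g
    var = sy**2 / g**2
    if second_order:
        var += G**2 * sx**2 / g**4
    return MrEstimate.from_beta_se("Wald ratio", beta, math.sqrt(var), 1)


def _ivw_core(bx, sx, by, sy, model: str):
    ratios = by / bx
    w = (bx / sy) ** 2  # 1/se1² with se1 = sy/|bx|
    sw = w.sum()
    beta = float((w * ratios).sum() / sw)
    se_fixed = sw**-0.5
    J = len(bx)
    q = float((w * (ratios - beta) ** 2).sum())
    if model == "fixed" or (model == "auto" and J <= 3):
        se = se_fixed
    else:
        se = se_fixed * math.sqrt(max(1.0, q / (J - 1))) if J > 1 else se_fixed
    return beta, float(se), q


def ivw(
    instruments: Sequence[HarmonizedInstrument],
    model: str = "auto",
) -> MrEstimate:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    With first-order weights this is exactly WLS of Γ on γ through the
    origin with weights σ_y⁻². ``model``: ``"fixed"``, ``"random"``
    (multiplicative overdispersion, SE inflated by √max(1, Q/(J−1))), or
    ``"auto"`` (random when J > 3, else fixed).
    """
    if len(instruments) == 0:
        raise EstimatorError("IVW needs at least one instrument")
    if model not in ("auto", "fixed", "random"):
        raise EstimatorError(f"unknown IVW model {model!r}")
    if any(i.beta_exposure == 0 for i in instruments):
        raise EstimatorError("zero exposure beta among instruments")
    bx, sx, by, sy = _arrays(instruments)
    beta, se, _ = _ivw_core(bx, sx, by, sy, model)
    return MrEstimate.from_beta_se("IVW", beta, se, len(instruments))


def mr_egger(instruments: Sequence[HarmonizedInstrument]) -> EggerEstimate:
    """MR-Egger: weighted regression Γ = α + βγ, weights σ_y⁻².

    Exposure effects are oriented non-negative first (flipping Γ with
    them), since the intercept is only meaningful for a consistent γ
    orientation. SEs carry a multiplicative overdispersion factor
    √max(1, RSS/(J−2)); p-values use t with J−2 df.
    """
    J = len(instruments)
    if J < 3:
        raise EstimatorError("MR-Egger needs at least 3 instruments")
    bx, sx, by, sy = _arrays(instruments)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = sy**-2.0
    X = np.column_stack([np.ones(J), bx])
    XtW = X.T * w
    xtwx = XtW @ X
    coef = np.linalg.solve(xtwx, XtW @ by)
    resid = by - X @ coef
    rss = float((w * resid**2).sum())
    phi = max(1.0, rss / (J - 2))
    cov = np.linalg.inv(xtwx) * phi
    alpha, beta = float(coef[0]), float(coef[1])
    se_a, se_b = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    slope = MrEstimate.from_beta_se("MR-Egger", beta, se_b, J, df=J - 2)
    crit = stats.t.ppf(0.975, J - 2)
    p_a = float(2 * stats.t.sf(abs(alpha / se_a), J - 2)) if se_a > 0 else 1.0
    return EggerEstimate(
        slope=slope,
        intercept=alpha,
        intercept_se=se_a,
        intercept_ci_low=alpha - crit * se_a,
        intercept_ci_high=alpha + crit * se_a,
        intercept_pvalue=p_a,
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    b = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(0.5, s, b))


def median_estimator(
    instruments: Sequence[HarmonizedInstrument],
    weighted: bool = True,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MrEstimate:
    """Simple or (inverse-variance-)weighted median of the Wald ratios.

    The estimate interpolates the ordered ratios at cumulative
    standardized weight 0.5; its SE comes from a parametric bootstrap
    resampling each γ_j and Γ_j from their reported normals.
    """
    J = len(instruments)
    if J < 3:
        raise EstimatorError("median estimator needs at least 3 instruments")
    if seed is None:
        raise EstimatorError("median estimator bootstrap requires an explicit seed")
    bx, sx, by, sy = _arrays(instruments)

    def weights_of(bx_, sy_):
        return (bx_ / sy_) ** 2 if weighted else np.full(J, 1.0 / J)

    est = _weighted_median(by / bx, weights_of(bx, sy))
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, J))
    by_b = rng.normal(by, sy, size=(n_boot, J))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _weighted_median(by_b[b] / bx_b[b], weights_of(bx_b[b], sy))
    se = float(boots.std(ddof=1))
    label = "Weighted median" if weighted else "Simple median"
    return MrEstimate.from_beta_se(label, est, se, J)


def _mode_bandwidth(ratios: np.ndarray, se_ratios: np.ndarray, phi: float) -> float:
    # modified Silverman rule on the ratio scale
    s = np.std(ratios, ddof=1) if len(ratios) > 1 else 0.0
    mad = stats.median_abs_deviation(ratios, scale="normal")
    spread = min(s, mad) if mad > 0 else s
    if spread <= 0:
        return 0.0
    return float(phi * 0.9 * spread * len(ratios) ** (-1 / 5))


def _kde_argmax(ratios: np.ndarray, weights: np.ndarray, h: float) -> float:
    if h <= 0:
        # degenerate: all ratios (effectively) identical
        return float(np.average(ratios, weights=weights))
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = (weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2)).sum(0)
    x0 = grid[int(np.argmax(dens))]
    step = grid[1] - grid[0]

    def neg_dens(x):
        return -(weights * np.exp(-0.5 * ((x - ratios) / h) ** 2)).sum()

    # xatol tied to the grid step so refinement precision scales with the data
    res = optimize.minimize_scalar(
        neg_dens, bounds=(x0 - step, x0 + step), method="bounded",
        options={"xatol": step * 1e-8},
    )
    return float(res.x) if res.fun <= neg_dens(x0) else float(x0)


def mode_estimator(
    instruments: Sequence[HarmonizedInstrument],
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MrEstimate:
    """Mode-based estimate: argmax of a normal-kernel density over the
    Wald ratios, with equal (simple) or inverse-variance (weighted)
    kernel weights and a modified-Silverman bandwidth scaled by
    ``bandwidth_factor`` (φ). SE by parametric bootstrap.
    """
    J = len(instruments)
    if J < 3:
        raise EstimatorError("mode estimator needs at least 3 instruments")
    if seed is None:
        raise EstimatorError("mode estimator bootstrap requires an explicit seed")
    bx, sx, by, sy = _arrays(instruments)

    def point(bx_, by_):
        ratios = by_ / bx_
        se1 = sy / np.abs(bx_)
        w = se1**-2.0 if weighted else np.full(J, 1.0)
        h = _mode_bandwidth(ratios, se1, bandwidth_factor)
        return _kde_argmax(ratios, w / w.sum(), h)

    est = point(bx, by)
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, J))
    by_b = rng.normal(by, sy, size=(n_boot, J))
    boots = np.array([point(bx_b[b], by_b[b]) for b in range(n_boot)])
    se = float(boots.std(ddof=1))
    label = "Weighted mode" if weighted else "Simple mode"
    return MrEstimate.from_beta_se(label, est, se, J)


def _ml_profile_negll(beta: float, bx, sx, by, sy) -> float:
    # profile over the latent true exposure effects: for fixed beta the
    # optimum gives residuals (Γ - βγ) with variance σ_y² + β²σ_x²
    v = sy**2 + beta**2 * sx**2
    return float(0.5 * (((by - beta * bx) ** 2) / v).sum())


def max_likelihood(instruments: Sequence[HarmonizedInstrument]) -> MrEstimate:
    """Maximum-likelihood estimate under the bivariate normal model
    γ_j ~ N(γ̂_j, σ_xj²), Γ_j ~ N(βγ̂_j, σ_yj²).

    The latent γ̂_j are profiled out analytically; β is found by a
    deterministic 1-D minimization started at the fixed-effects IVW
    value, and the SE comes from the numerical curvature of the profile
    log-likelihood at the optimum.
    """
    J = len(instruments)
    if J < 2:
        raise EstimatorError("maximum likelihood needs at least 2 instruments")
    bx, sx, by, sy = _arrays(instruments)
    b0, _, _ = _ivw_core(bx, sx, by, sy, "fixed")
    res = optimize.minimize(
        _ml_profile_negll, x0=[b0], args=(bx, sx, by, sy), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12},
    )
    if not res.success:
        raise EstimatorError(f"maximum likelihood failed to converge: {res.message}")
    beta = float(res.x[0])
    h = max(1e-5, 1e-5 * abs(beta))
    f = lambda b: _ml_profile_negll(b, bx, sx, by, sy)
    curv = (f(beta + h) - 2 * f(beta) + f(beta - h)) / h**2
    if curv <= 0:
        raise EstimatorError("maximum likelihood: non-positive information at optimum")
    se = curv**-0.5
    return MrEstimate.from_beta_se("Maximum likelihood", beta, se, J)


def estimate_all(
    instruments: Sequence[HarmonizedInstrument],
    ivw_model: str = "auto",
    n_boot: int = 1000,
    bandwidth_factor: float = 1.0,
    seed: int = 0,
) -> tuple[list[MrEstimate], dict[str, str]]:
    """Run the full estimator suite; one labeled estimate per method.

    Returns the estimates (forest-plot-ready) and a dict of methods that
    were skipped because their preconditions failed, with the reason. A
    failing method never aborts the suite.
    """
    runners = [
        ("IVW", lambda: ivw(instruments, model=ivw_model)),
        ("Maximum likelihood", lambda: max_likelihood(instruments)),
        ("Simple median", lambda: median_estimator(instruments, weighted=False, n_boot=n_boot, seed=seed)),
        ("Weighted median", lambda: median_estimator(instruments, weighted=True, n_boot=n_boot, seed=seed + 1)),
        ("Simple mode", lambda: mode_estimator(instruments, weighted=False, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed + 2)),
        ("Weighted mode", lambda: mode_estimator(instruments, weighted=True, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed + 3)),
        ("MR-Egger", lambda: mr_egger(instruments).slope),
    ]
    estimates: list[MrEstimate] = []
    skipped: dict[str, str] = {}
    for name, run in runners:
        try:
            estimates.append(run())
        except EstimatorError as exc:
            skipped[name] = str(exc)
    return estimates, skipped


def estimates_to_frame(estimates: Sequence[MrEstimate]) -> pd.DataFrame:
    """Serialize estimates to the forest-layout results table."""
    return pd.DataFrame(
        [
            {
                "method": e.method,
                "n_snps": e.n_snps,
                "beta": e.beta,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pvalue": e.pvalue,
                "or": e.or_value,
                "or_low": e.or_low,
                "or_high": e.or_high,
            }
            for e in estimates
        ]
    )
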