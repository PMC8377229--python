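"""End-to-end orchestration: selection → estimation → diagnostics →
multivariable MR/mediation → power, with a reproducible report bundle.

Every output table is plain delimited text and the run report echoes the
full configuration and seed, so a report regenerates itself exactly.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import cochran_q, egger_intercept_test, funnel_data, leave_one_out, mr_presso
from .estimators import EstimatorError, estimate_all, estimates_to_frame, ivw, mr_egger
from .instrument_selection import (
    LdMatrix,
    SelectionConfig,
    read_ld_table,
    select_instruments,
)
from .mvmr import mediation_decompose, mvmr_ivw, mvmr_to_frame
from .power import PowerParams, mr_power_binary
from .summary_data import GwasTableError, read_gwas_table, read_proxy_table

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    exposure: str
    outcome: str
    out_dir: str
    seed: int
    mediator: Optional[str] = None
    ld: Optional[str] = None
    proxies: Optional[str] = None
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    f_min: float = 10.0
    proxy_r2: float = 0.8
    drop_palindromic: bool = True
    ivw_model: str = "auto"
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    presso_n_sim: int = 1000
    presso_outlier_threshold: float = 0.05
    run_presso: bool = True
    #: optional power section: true odds ratio (and optionally r2_xz;
    #: estimated from the instruments when omitted), case_fraction, alpha
    power_true_or: Optional[float] = None
    power_r2_xz: Optional[float] = None
    power_case_fraction: Optional[float] = None
    power_alpha: float = 0.05
    column_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("exposure", "outcome"):
            path = getattr(self, name)
            if not path:
                raise ValueError(f"config field {name!r} is required")
            if not Path(path).exists():
                raise FileNotFoundError(f"config field {name!r}: file not found: {path}")
        for name in ("mediator", "ld", "proxies"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config field {name!r}: file not found: {path}")
        if self.seed is None:
            raise ValueError("config field 'seed' is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


def _estimated_r2_xz(instruments, exposure) -> float:
    """Exposure variance explained by the instruments,
    Σ 2·EAF(1−EAF)·γ² (SNPs with missing EAF contribute via MAF 0.3)."""
    total = 0.0
    for inst in instruments:
        rec = exposure.get(inst.rsid)
        eaf = rec.eaf if rec is not None and rec.eaf is not None else 0.3
        total += 2 * eaf * (1 - eaf) * inst.beta_exposure**2
    return total


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict and writes the
    bundle (tables + run_report.json) under ``config.out_dir``.

    Any stage failure raises with a stage-labeled message; outputs
    produced before the failure are already flushed to disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": {"name": "tsmr", "version": __version__, "python": platform.python_version()},
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
    }

    def _flush():
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    report["failed_stage"] = {"stage": name, "error": str(exc)}
                    _flush()
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    with _stage("read inputs"):
        exposure = read_gwas_table(config.exposure, "exposure", config.column_map or None)
        outcome = read_gwas_table(config.outcome, "outcome", config.column_map or None)
        mediator = (
            read_gwas_table(config.mediator, "mediator", config.column_map or None)
            if config.mediator
            else None
        )
        proxies = read_proxy_table(config.proxies) if config.proxies else None
        ld = (
            read_ld_table(config.ld, rsids=exposure.rsids)
            if config.ld
            else LdMatrix.identity(exposure.rsids)
        )

    sel_config = SelectionConfig(
        p_threshold=config.p_threshold,
        clump_r2=config.clump_r2,
        f_min=config.f_min,
        proxy_r2=config.proxy_r2,
        drop_palindromic=config.drop_palindromic,
    )
    with _stage("instrument selection"):
        instruments, sel_report = select_instruments(
            exposure, outcome, ld, sel_config, mediator=mediator, proxies=proxies
        )
        report["selection"] = sel_report.to_dict()
        pd.DataFrame(
            [
                {
                    "rsid": i.rsid,
                    "effect_allele": i.effect_allele,
                    "beta_exposure": i.beta_exposure,
                    "se_exposure": i.se_exposure,
                    "beta_outcome": i.beta_outcome,
                    "se_outcome": i.se_outcome,
                    "beta_mediator": i.beta_mediator,
                    "se_mediator": i.se_mediator,
                    "proxy_of": i.proxy_of,
                }
                for i in instruments
            ]
        ).to_csv(out / "instruments.tsv", sep="\t", index=False)
        _flush()

    with _stage("causal estimation"):
        estimates, skipped = estimate_all(
            instruments,
            ivw_model=config.ivw_model,
            n_boot=config.n_boot,
            bandwidth_factor=config.bandwidth_factor,
            seed=config.seed,
        )
        est_frame = estimates_to_frame(estimates)
        est_frame.to_csv(out / "estimates.tsv", sep="\t", index=False)
        report["estimates"] = est_frame.to_dict(orient="records")
        report["estimates_skipped"] = skipped
        report["primary"] = "IVW"
        _flush()

    with _stage("sensitivity diagnostics"):
        diagnostics: dict = {}
        try:
            intercept = egger_intercept_test(instruments)
            diagnostics["egger_intercept"] = {
                "intercept": intercept.intercept,
                "se": intercept.se,
                "ci_low": intercept.ci_low,
                "ci_high": intercept.ci_high,
                "pvalue": intercept.pvalue,
                "no_directional_pleiotropy": intercept.no_directional_pleiotropy,
            }
        except EstimatorError as exc:
            diagnostics["egger_intercept"] = {"skipped": str(exc)}
        q = cochran_q(instruments)
        diagnostics["cochran_q"] = {"q": q.q, "df": q.df, "pvalue": q.pvalue}
        loo = leave_one_out(instruments, ivw_model=config.ivw_model)
        pd.DataFrame(
            [
                {
                    "rsid": rsid,
                    "beta": est.beta,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "flagged": rsid in loo.flagged,
                }
                for rsid, est in loo.estimates.items()
            ]
        ).to_csv(out / "leave_one_out.tsv", sep="\t", index=False)
        diagnostics["leave_one_out_flagged"] = loo.flagged
        funnel = funnel_data(instruments)
        funnel.to_csv(out / "funnel.tsv", sep="\t", index=False)
        diagnostics["funnel_ivw_beta"] = funnel.attrs["ivw_beta"]
        if config.run_presso:
            try:
                presso = mr_presso(
                    instruments,
                    n_sim=config.presso_n_sim,
                    outlier_threshold=config.presso_outlier_threshold,
                    seed=config.seed,
                    ivw_model=config.ivw_model,
                )
                diagnostics["mr_presso"] = {
                    "global_rss": presso.global_rss,
                    "global_p": presso.global_p,
                    "outliers": presso.outliers,
                    "corrected_beta": presso.corrected.beta,
                    "corrected_se": presso.corrected.se,
                    "corrected_n_snps": presso.corrected.n_snps,
                    "distortion_p": presso.distortion_p,
                }
                pd.DataFrame(
                    [
                        {"rsid": rsid, "outlier_p": p, "outlier": rsid in presso.outliers}
                        for rsid, p in presso.outlier_p.items()
                    ]
                ).to_csv(out / "presso_outliers.tsv", sep="\t", index=False)
            except EstimatorError as exc:
                diagnostics["mr_presso"] = {"skipped": str(exc)}
        report["diagnostics"] = diagnostics
        _flush()

    if mediator is not None:
        with _stage("multivariable MR and mediation"):
            mv = mvmr_ivw(
                instruments,
                ivw_model=config.ivw_model,
                labels=("exposure | mediator", "mediator | exposure"),
            )
            mvmr_frame = mvmr_to_frame(mv, "exposure", "mediator", "outcome")
            mvmr_frame.to_csv(out / "mvmr.tsv", sep="\t", index=False)
            total = ivw(instruments, model=config.ivw_model)
            mediation = mediation_decompose(total, mv.exposure)
            report["mvmr"] = mvmr_frame.to_dict(orient="records")
            report["mediation"] = {
                "total_beta": mediation.total_beta,
                "direct_beta": mediation.direct_beta,
                "indirect_beta": mediation.indirect_beta,
                "proportion_mediated": mediation.proportion_mediated,
                "percent_total": mediation.percent_total,
                "percent_direct": mediation.percent_direct,
            }
            _flush()

    if config.power_true_or is not None:
        with _stage("power"):
            n_out = max((i for i in outcome if i.n is not None), key=lambda r: r.n, default=None)
            r2 = config.power_r2_xz or _estimated_r2_xz(instruments, exposure)
            params = PowerParams(
                n=float(n_out.n) if n_out is not None else float(len(outcome)),
                case_fraction=config.power_case_fraction or 0.5,
                r2_xz=r2,
                true_or=config.power_true_or,
                alpha=config.power_alpha,
            )
            report["power"] = {
                "power": mr_power_binary(params),
                "params": asdict(params),
            }
            _flush()

    _flush()
    return report
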