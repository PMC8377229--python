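"""Instrument selection: significance filter, greedy LD clumping, F check.

A valid genetic instrument must be robustly associated with the exposure
(genome-wide significance, p < 5e-8), independent of the other
instruments (pairwise r² at or below a clumping threshold), and strong
(F statistic above 10, the conventional weak-instrument bar). The
pipeline applies, in order: significance filter → LD clumping →
harmonization with the outcome (palindrome drop, proxy substitution) →
F filter, and reports the count surviving each stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .summary_data import (
    GwasTable,
    GwasTableError,
    HarmonizationReport,
    HarmonizedInstrument,
    SnpAssociation,
    harmonize,
)

__all__ = [
    "LdMatrix",
    "SelectionConfig",
    "SelectionReport",
    "filter_significant",
    "ld_clump",
    "f_statistic",
    "select_instruments",
    "read_ld_table",
]


class LdMatrix:
    """Pairwise squared-correlation (r²) matrix over a set of rsids."""

    def __init__(self, rsids: Sequence[str], r2: np.ndarray):
        r2 = np.asarray(r2, dtype=float)
        n = len(rsids)
        if r2.shape != (n, n):
            raise ValueError(f"r2 must be {n}x{n}, got {r2.shape}")
        if not np.allclose(r2, r2.T, atol=1e-12):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0):
            raise ValueError("r2 diagonal must be exactly 1")
        if r2.min() < 0 or r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")
        self.rsids = list(rsids)
        if len(set(self.rsids)) != n:
            raise ValueError("duplicate rsids in LD matrix")
        self._index = {r: i for i, r in enumerate(self.rsids)}
        self.r2 = r2

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def value(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def identity(cls, rsids: Sequence[str]) -> "LdMatrix":
        """All SNPs mutually independent (r² = 0 off-diagonal)."""
        return cls(rsids, np.eye(len(rsids)))


def read_ld_table(path, rsids: Optional[Sequence[str]] = None, sep: str = "\t") -> LdMatrix:
    """Build an :class:`LdMatrix` from a sparse pair list.

    The file has columns ``rsid_a``, ``rsid_b``, ``r2``; absent pairs are
    treated as r² = 0. ``rsids`` extends the universe beyond the rsids
    named in the file (SNPs with no listed partner).
    """
    df = pd.read_csv(path, sep=sep)
    missing = {"rsid_a", "rsid_b", "r2"} - set(df.columns)
    if missing:
        raise GwasTableError(f"{path}: LD table missing columns {sorted(missing)}")
    universe: list[str] = list(rsids) if rsids is not None else []
    seen = set(universe)
    for col in ("rsid_a", "rsid_b"):
        for r in df[col].astype(str):
            if r not in seen:
                seen.add(r)
                universe.append(r)
    idx = {r: i for i, r in enumerate(universe)}
    mat = np.eye(len(universe))
    for row in df.itertuples(index=False):
        i, j = idx[str(row.rsid_a)], idx[str(row.rsid_b)]
        mat[i, j] = mat[j, i] = float(row.r2)
    return LdMatrix(universe, mat)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the instrument-selection pipeline."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    f_min: float = 10.0
    proxy_r2: float = 0.8
    drop_palindromic: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must lie in (0, 1]")
        if not (0 <= self.clump_r2 <= 1):
            raise ValueError("clump_r2 must lie in [0, 1]")
        if not (0 <= self.proxy_r2 <= 1):
            raise ValueError("proxy_r2 must lie in [0, 1]")
        if self.f_min < 0:
            raise ValueError("f_min must be non-negative")


@dataclass
class SelectionReport:
    """Counts at every stage of instrument selection; stages telescope."""

    n_input: int = 0
    n_significant: int = 0
    n_after_clump: int = 0
    n_after_harmonization: int = 0
    n_final: int = 0
    harmonization: Optional[HarmonizationReport] = None
    weak_rsids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "n_input": self.n_input,
            "n_significant": self.n_significant,
            "n_after_clump": self.n_after_clump,
            "n_after_harmonization": self.n_after_harmonization,
            "n_final": self.n_final,
            "weak_rsids": list(self.weak_rsids),
        }
        if self.harmonization is not None:
            h = self.harmonization
            d["harmonization"] = {
                "n_input": h.n_input,
                "n_flipped": h.n_flipped,
                "n_palindromic_dropped": h.n_palindromic_dropped,
                "n_unmatched_dropped": h.n_unmatched_dropped,
                "n_proxied": h.n_proxied,
                "dropped_rsids": list(h.dropped_rsids),
            }
        return d


def filter_significant(table: GwasTable, p_threshold: float = 5e-8) -> GwasTable:
    """Rows with p strictly below the threshold, input order preserved."""
    kept = [r for r in table if r.pvalue < p_threshold]
    if not kept:
        warnings.warn(
            f"no SNP in {table.trait_label!r} reaches p < {p_threshold:g}", stacklevel=2
        )
    return GwasTable(table.trait_label, kept)


def ld_clump(table: GwasTable, ld: LdMatrix, clump_r2: float = 0.001) -> GwasTable:
    """Greedy LD clumping.

    SNPs are visited by ascending p-value (rsid as deterministic
    tie-break); a SNP is accepted iff its r² with every already-accepted
    SNP is at or below ``clump_r2``. Output keeps acceptance order.
    """
    missing = [r.rsid for r in table if r.rsid not in ld]
    if missing:
        raise KeyError(f"rsids missing from LD matrix: {missing[:5]}")
    ordered = sorted(table, key=lambda r: (r.pvalue, r.rsid))
    accepted: list[SnpAssociation] = []
    for rec in ordered:
        if all(ld.value(rec.rsid, a.rsid) <= clump_r2 for a in accepted):
            accepted.append(rec)
    return GwasTable(table.trait_label, accepted)


def f_statistic(assoc) -> float:
    """Instrument-strength F statistic, the summary-data form (beta/se)²."""
    if hasattr(assoc, "se_exposure"):
        return (assoc.beta_exposure / assoc.se_exposure) ** 2
    return (assoc.beta / assoc.se) ** 2


def select_instruments(
    exposure: GwasTable,
    outcome: GwasTable,
    ld: LdMatrix,
    config: SelectionConfig = SelectionConfig(),
    mediator: Optional[GwasTable] = None,
    proxies: Optional[pd.DataFrame] = None,
) -> tuple[list[HarmonizedInstrument], SelectionReport]:
    """Full instrument-selection pipeline.

    Applies the significance filter, greedy LD clumping, harmonization
    with the outcome (palindrome removal and proxy substitution), and the
    weak-instrument F filter, in that order. The returned report records
    the SNP count surviving each stage.
    """
    report = SelectionReport(n_input=len(exposure))
    sig = filter_significant(exposure, config.p_threshold)
    report.n_significant = len(sig)
    clumped = ld_clump(sig, ld, config.clump_r2)
    report.n_after_clump = len(clumped)
    instruments, harm_report = harmonize(
        clumped,
        outcome,
        mediator=mediator,
        drop_palindromic=config.drop_palindromic,
        proxies=proxies,
        proxy_r2=config.proxy_r2,
    )
    report.harmonization = harm_report
    report.n_after_harmonization = len(instruments)
    strong = [inst for inst in instruments if f_statistic(inst) > config.f_min]
    report.weak_rsids = [
        inst.rsid for inst in instruments if f_statistic(inst) <= config.f_min
    ]
    report.n_final = len(strong)
    if not strong:
        raise GwasTableError("no instruments survive selection; analysis impossible")
    return strong, report
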