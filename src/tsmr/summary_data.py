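"""GWAS summary-statistics containers, table IO and allele harmonization.

Two-sample MR combines per-SNP association estimates from separate GWAS
cohorts. Before any estimator can run, the exposure and outcome (and,
for multivariable MR, mediator) tables must be aligned to a common
effect allele: effect sizes reported for opposite alleles are negated,
strand flips are resolved by complementing, and palindromic SNPs
(A/T, C/G), whose strand is ambiguous, are dropped by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "SnpAssociation",
    "GwasTable",
    "HarmonizedInstrument",
    "HarmonizationReport",
    "GwasTableError",
    "read_gwas_table",
    "write_gwas_table",
    "read_proxy_table",
    "is_palindromic",
    "complement_allele",
    "substitute_proxy",
    "harmonize",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for delimited GWAS tables
CANONICAL_COLUMNS = (
    "rsid",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)


class GwasTableError(ValueError):
    """Raised for malformed GWAS summary-statistics input."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's association with one trait.

    ``beta`` is the additive per-effect-allele estimate: log-odds for a
    binary trait, SD units for a quantitative trait.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise GwasTableError("rsid must be non-empty")
        for name, allele in (
            ("effect_allele", self.effect_allele),
            ("other_allele", self.other_allele),
        ):
            if allele not in _VALID_ALLELES:
                raise GwasTableError(
                    f"{self.rsid}: {name} {allele!r} is not a single base A/C/G/T"
                )
        if self.effect_allele == self.other_allele:
            raise GwasTableError(f"{self.rsid}: effect and other allele are identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise GwasTableError(f"{self.rsid}: se must be finite and > 0, got {self.se}")
        if not math.isfinite(self.beta):
            raise GwasTableError(f"{self.rsid}: beta must be finite")
        if not (0 < self.pvalue <= 1):
            raise GwasTableError(f"{self.rsid}: pvalue must lie in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise GwasTableError(f"{self.rsid}: eaf must lie in [0, 1], got {self.eaf}")
        if self.n is not None and self.n <= 0:
            raise GwasTableError(f"{self.rsid}: n must be positive, got {self.n}")

    @property
    def is_palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)

    def flipped(self) -> "SnpAssociation":
        """The same association expressed on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )

    def complemented(self) -> "SnpAssociation":
        """The same association on the opposite strand (betas unchanged)."""
        return replace(
            self,
            effect_allele=_COMPLEMENT[self.effect_allele],
            other_allele=_COMPLEMENT[self.other_allele],
        )


class GwasTable:
    """An ordered collection of :class:`SnpAssociation`, unique by rsid."""

    def __init__(self, trait_label: str, records: Iterable[SnpAssociation]):
        if not trait_label:
            raise GwasTableError("trait_label must be non-empty")
        self.trait_label = trait_label
        self._records: dict[str, SnpAssociation] = {}
        for rec in records:
            if rec.rsid in self._records:
                raise GwasTableError(f"duplicate rsid {rec.rsid!r} in {trait_label} table")
            self._records[rec.rsid] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._records

    def get(self, rsid: str) -> Optional[SnpAssociation]:
        return self._records.get(rsid)

    @property
    def rsids(self) -> list[str]:
        return list(self._records)

    def subset(self, rsids: Sequence[str]) -> "GwasTable":
        """Rows for ``rsids`` in the given order; unknown rsids are an error."""
        missing = [r for r in rsids if r not in self._records]
        if missing:
            raise KeyError(f"rsids not in {self.trait_label} table: {missing[:5]}")
        return GwasTable(self.trait_label, (self._records[r] for r in rsids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rsid": r.rsid,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "eaf": r.eaf,
                    "beta": r.beta,
                    "se": r.se,
                    "pvalue": r.pvalue,
                    "n": r.n,
                }
                for r in self
            ],
            columns=list(CANONICAL_COLUMNS),
        )


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP's aligned exposure/outcome (and optional mediator) effects."""

    rsid: str
    effect_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    beta_mediator: Optional[float] = None
    se_mediator: Optional[float] = None
    proxy_of: Optional[str] = None

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise GwasTableError(f"{self.rsid}: harmonized SEs must be > 0")
        if self.se_mediator is not None and self.se_mediator <= 0:
            raise GwasTableError(f"{self.rsid}: mediator SE must be > 0")
        if self.proxy_of is not None and self.proxy_of == self.rsid:
            raise GwasTableError(f"{self.rsid}: proxy_of must differ from rsid")


@dataclass
class HarmonizationReport:
    """Audit trail of the harmonization step; counts telescope exactly."""

    n_input: int = 0
    n_flipped: int = 0
    n_palindromic_dropped: int = 0
    n_unmatched_dropped: int = 0
    n_proxied: int = 0
    dropped_rsids: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_palindromic_dropped - self.n_unmatched_dropped


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous: {A,T} or {C,G}."""
    for name, a in (("a1", a1), ("a2", a2)):
        if a not in _VALID_ALLELES:
            raise GwasTableError(f"{name}={a!r} is not a single base A/C/G/T")
    return _COMPLEMENT[a1] == a2


def complement_allele(a: str) -> str:
    if a not in _VALID_ALLELES:
        raise GwasTableError(f"{a!r} is not a single base A/C/G/T")
    return _COMPLEMENT[a]


def _parse_optional(value, cast):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "NaN", "nan", "."):
        return None
    return cast(value)


def read_gwas_table(
    path,
    trait_label: str = "trait",
    column_map: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = None,
) -> GwasTable:
    """Read a delimited GWAS summary-statistics table.

    Parameters
    ----------
    path
        Tab- or comma-separated file with a header row.
    trait_label
        Name attached to the resulting table.
    column_map
        Mapping from canonical names (``rsid``, ``effect_allele``,
        ``other_allele``, ``eaf``, ``beta``, ``se``, ``pvalue``, ``n``)
        to the source file's headers, for non-canonical dialects.
    sep
        Field separator; inferred (tab, then comma) when omitted.

    Rows violating the per-SNP invariants are rejected with row-indexed
    messages collected into a single :class:`GwasTableError`.
    """
    if sep is None:
        sep = r"[\t,]"
        df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=sep, dtype=str)
    colmap = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = colmap.get(canon, canon)
        if src in df.columns:
            rename[src] = canon
        elif canon in ("rsid", "effect_allele", "other_allele", "beta", "se", "pvalue"):
            raise GwasTableError(f"{path}: required column {src!r} (for {canon}) not found")
    df = df.rename(columns=rename)

    records: list[SnpAssociation] = []
    errors: list[str] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        try:
            row_d = row._asdict()
            ea = str(row_d["effect_allele"]).strip().upper()
            oa = str(row_d["other_allele"]).strip().upper()
            if len(ea) != 1 or len(oa) != 1:
                raise GwasTableError("indel or multi-allelic variant (alleles must be single bases)")
            rec = SnpAssociation(
                rsid=str(row_d["rsid"]).strip(),
                effect_allele=ea,
                other_allele=oa,
                beta=float(row_d["beta"]),
                se=float(row_d["se"]),
                pvalue=float(row_d["pvalue"]),
                eaf=_parse_optional(row_d.get("eaf"), float),
                n=_parse_optional(row_d.get("n"), lambda v: int(float(v))),
            )
            if rec.rsid in seen:
                raise GwasTableError(f"duplicate rsid {rec.rsid!r}")
            seen.add(rec.rsid)
            records.append(rec)
        except (GwasTableError, ValueError, KeyError) as exc:
            errors.append(f"line {idx}: {exc}")
    if errors:
        raise GwasTableError(
            f"{path}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors)
        )
    if not records:
        raise GwasTableError(f"{path}: zero valid rows")
    return GwasTable(trait_label, records)


def write_gwas_table(table: GwasTable, path, sep: str = "\t") -> None:
    table.to_frame().to_csv(path, sep=sep, index=False)


def read_proxy_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a proxy table: target_rsid, proxy_rsid, r2, and the proxy
    allele corresponding to the target's effect allele."""
    df = pd.read_csv(path, sep=sep)
    required = {
        "target_rsid",
        "proxy_rsid",
        "r2",
        "proxy_effect_allele_for_target_effect_allele",
    }
    missing = required - set(df.columns)
    if missing:
        raise GwasTableError(f"{path}: proxy table missing columns {sorted(missing)}")
    return df


def substitute_proxy(
    rsid: str,
    outcome: GwasTable,
    proxies: pd.DataFrame,
    proxy_r2: float = 0.8,
) -> Optional[SnpAssociation]:
    """Best-r² proxy for ``rsid`` present in the outcome table.

    Returns the proxy's association re-expressed on the target's alleles
    (rsid rewritten to the target, beta oriented to the target's effect
    allele via the supplied allele correspondence), or ``None`` when no
    proxy with r² > ``proxy_r2`` is available.
    """
    cand = proxies[proxies["target_rsid"] == rsid]
    cand = cand[cand["r2"] > proxy_r2].sort_values("r2", ascending=False)
    for row in cand.itertuples(index=False):
        assoc = outcome.get(str(row.proxy_rsid))
        if assoc is None:
            continue
        mapped_allele = str(row.proxy_effect_allele_for_target_effect_allele).upper()
        if mapped_allele not in _VALID_ALLELES:
            raise GwasTableError(
                f"proxy row {row.proxy_rsid}->{rsid}: bad allele {mapped_allele!r}"
            )
        if assoc.effect_allele == mapped_allele:
            oriented = assoc
        elif assoc.other_allele == mapped_allele:
            oriented = assoc.flipped()
        else:
            comp = assoc.complemented()
            if comp.effect_allele == mapped_allele:
                oriented = comp
            elif comp.other_allele == mapped_allele:
                oriented = comp.flipped()
            else:
                continue
        # oriented so that its effect allele corresponds to the target's
        # effect allele; keeps the proxy's own rsid and base letters
        return oriented
    return None


def _align(exposure: SnpAssociation, other: SnpAssociation) -> Optional[SnpAssociation]:
    """Orient ``other`` onto the exposure's allele pair, or None if unmatched."""
    exp_pair = (exposure.effect_allele, exposure.other_allele)
    for cand in (other, other.complemented()):
        if (cand.effect_allele, cand.other_allele) == exp_pair:
            return cand
        if (cand.other_allele, cand.effect_allele) == exp_pair:
            return cand.flipped()
    return None


def harmonize(
    exposure: GwasTable,
    outcome: GwasTable,
    mediator: Optional[GwasTable] = None,
    drop_palindromic: bool = True,
    proxies: Optional[pd.DataFrame] = None,
    proxy_r2: float = 0.8,
) -> tuple[list[HarmonizedInstrument], HarmonizationReport]:
    """Align outcome (and mediator) effects to the exposure's effect alleles.

    For each exposure SNP found in the outcome table (directly, or through
    a qualifying proxy), the outcome row is oriented onto the exposure's
    allele pair by swapping (negating beta) and/or strand-complementing;
    SNPs whose alleles cannot be reconciled are dropped as unmatched.
    Palindromic SNPs are dropped when ``drop_palindromic`` (the default,
    since their strand cannot be verified across cohorts). When a mediator
    table is supplied, SNPs missing from it are likewise dropped as
    unmatched.
    """
    if len(exposure) == 0:
        raise GwasTableError("exposure table is empty")
    report = HarmonizationReport(n_input=len(exposure))
    instruments: list[HarmonizedInstrument] = []
    for exp in exposure:
        if drop_palindromic and exp.is_palindromic:
            report.n_palindromic_dropped += 1
            report.dropped_rsids.append((exp.rsid, "palindromic"))
            continue
        proxy_rsid = None
        out = outcome.get(exp.rsid)
        if out is not None:
            aligned = _align(exp, out)
            if aligned is None:
                report.n_unmatched_dropped += 1
                report.dropped_rsids.append((exp.rsid, "allele mismatch with outcome"))
                continue
            if aligned.beta != out.beta:
                report.n_flipped += 1
        else:
            proxy = None
            if proxies is not None:
                proxy = substitute_proxy(exp.rsid, outcome, proxies, proxy_r2=proxy_r2)
            if proxy is None:
                report.n_unmatched_dropped += 1
                report.dropped_rsids.append((exp.rsid, "absent from outcome"))
                continue
            # the proxy is already oriented onto the target's effect allele
            aligned = proxy
            proxy_rsid = proxy.rsid

        med_beta = med_se = None
        if mediator is not None:
            med = mediator.get(exp.rsid)
            med_aligned = None if med is None else _align(exp, med)
            if med_aligned is None:
                report.n_unmatched_dropped += 1
                report.dropped_rsids.append((exp.rsid, "absent from or mismatched in mediator"))
                continue
            med_beta, med_se = med_aligned.beta, med_aligned.se

        if proxy_rsid is not None:
            report.n_proxied += 1
        instruments.append(
            HarmonizedInstrument(
                rsid=exp.rsid,
                effect_allele=exp.effect_allele,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=aligned.beta,
                se_outcome=aligned.se,
                beta_mediator=med_beta,
                se_mediator=med_se,
                proxy_of=proxy_rsid,
            )
        )
    return instruments, report
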