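"""Table IO and allele-harmonization behaviour."""

import math

import numpy as np
import pytest

from tsmr.estimators import ivw
from tsmr.summary_data import (
    GwasTable,
    GwasTableError,
    harmonize,
    is_palindromic,
    read_gwas_table,
    read_proxy_table,
    substitute_proxy,
)

from conftest import make_assoc


class TestReadGwasTable:
    def test_well_formed_tsv(self, tmp_path):
        p = tmp_path / "gwas.tsv"
        p.write_text(
            "rsid\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
            "rs1\tA\tG\t0.3\t0.05\t0.005\t1e-9\t100000\n"
            "rs2\tT\tC\t0.4\t-0.02\t0.004\t1e-8\t100000\n"
            "rs3\tc\ta\tNA\t0.01\t0.006\t0.5\tNA\n"
        )
        table = read_gwas_table(p, "bw")
        assert len(table) == 3
        rec = table.get("rs3")
        assert rec.effect_allele == "C" and rec.eaf is None and rec.n is None

    def test_column_map_dialect(self, tmp_path):
        p = tmp_path / "gwas.csv"
        p.write_text("SNP,EA,NEA,b,stderr,P\nrs1,A,G,0.05,0.005,1e-9\n")
        table = read_gwas_table(
            p,
            column_map={
                "rsid": "SNP", "effect_allele": "EA", "other_allele": "NEA",
                "beta": "b", "se": "stderr", "pvalue": "P",
            },
        )
        assert table.get("rs1").beta == 0.05

    def test_zero_se_row_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "gwas.tsv"
        p.write_text(
            "rsid\teffect_allele\tother_allele\tbeta\tse\tpvalue\n"
            "rs1\tA\tG\t0.05\t0.005\t1e-9\n"
            "rs2\tA\tG\t0.05\t0\t1e-9\n"
        )
        with pytest.raises(GwasTableError, match="line 3"):
            read_gwas_table(p)

    def test_duplicate_rsid_names_the_rsid(self, tmp_path):
        p = tmp_path / "gwas.tsv"
        p.write_text(
            "rsid\teffect_allele\tother_allele\tbeta\tse\tpvalue\n"
            "rs1\tA\tG\t0.05\t0.005\t1e-9\n"
            "rs1\tT\tC\t0.02\t0.004\t1e-9\n"
        )
        with pytest.raises(GwasTableError, match="rs1"):
            read_gwas_table(p)

    def test_indel_rejected(self, tmp_path):
        p = tmp_path / "gwas.tsv"
        p.write_text(
            "rsid\teffect_allele\tother_allele\tbeta\tse\tpvalue\n"
            "rs1\tAT\tG\t0.05\t0.005\t1e-9\n"
        )
        with pytest.raises(GwasTableError, match="indel"):
            read_gwas_table(p)

    def test_missing_column_error(self, tmp_path):
        p = tmp_path / "gwas.tsv"
        p.write_text("rsid\tbeta\nrs1\t0.05\n")
        with pytest.raises(GwasTableError, match="effect_allele"):
            read_gwas_table(p)


@pytest.mark.parametrize(
    "a1,a2,expected",
    [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
     ("A", "G", False), ("A", "C", False), ("T", "G", False)],
)
def test_is_palindromic(a1, a2, expected):
    assert is_palindromic(a1, a2) is expected


def test_is_palindromic_rejects_non_acgt():
    with pytest.raises(GwasTableError):
        is_palindromic("A", "N")


class TestHarmonize:
    def test_swapped_alleles_negate_outcome_beta(self):
        exp = GwasTable("x", [make_assoc("rs1", "A", "G", beta=0.10)])
        out = GwasTable("y", [make_assoc("rs1", "G", "A", beta=-0.05)])
        insts, report = harmonize(exp, out)
        assert len(insts) == 1
        assert insts[0].effect_allele == "A"
        assert insts[0].beta_outcome == pytest.approx(0.05)
        assert report.n_flipped == 1

    def test_strand_complement_then_match(self):
        exp = GwasTable("x", [make_assoc("rs1", "A", "G", beta=0.10)])
        out = GwasTable("y", [make_assoc("rs1", "T", "C", beta=0.07)])
        insts, _ = harmonize(exp, out)
        assert insts[0].beta_outcome == pytest.approx(0.07)

    def test_strand_complement_and_swap(self):
        exp = GwasTable("x", [make_assoc("rs1", "A", "G", beta=0.10)])
        out = GwasTable("y", [make_assoc("rs1", "C", "T", beta=0.07)])
        insts, _ = harmonize(exp, out)
        assert insts[0].beta_outcome == pytest.approx(-0.07)

    def test_palindromic_dropped_by_default(self):
        exp = GwasTable(
            "x",
            [make_assoc("rs12623454", "A", "T", eaf=0.3), make_assoc("rs2", "A", "G")],
        )
        out = GwasTable(
            "y",
            [make_assoc("rs12623454", "A", "T", eaf=0.3), make_assoc("rs2", "A", "G")],
        )
        insts, report = harmonize(exp, out)
        assert [i.rsid for i in insts] == ["rs2"]
        assert report.n_palindromic_dropped == 1
        insts_keep, _ = harmonize(exp, out, drop_palindromic=False)
        assert len(insts_keep) == 2

    def test_irreconcilable_alleles_dropped_and_reported(self):
        exp = GwasTable("x", [make_assoc("rs1", "A", "G")])
        out = GwasTable("y", [make_assoc("rs1", "A", "C")])
        insts, report = harmonize(exp, out)
        assert insts == []
        assert report.n_unmatched_dropped == 1
        assert report.dropped_rsids[0][0] == "rs1"

    def test_idempotence_on_aligned_tables(self, small_table):
        out = GwasTable("y", [make_assoc(r.rsid, r.effect_allele, r.other_allele, beta=0.3 * r.beta) for r in small_table])
        first, _ = harmonize(small_table, out)
        second, _ = harmonize(small_table, out)
        assert first == second

    def test_strand_involution(self, small_table):
        """Complementing both outcome alleles (betas untouched) changes nothing."""
        out = GwasTable("y", [make_assoc(r.rsid, r.effect_allele, r.other_allele, beta=0.3 * r.beta) for r in small_table])
        comp = GwasTable("y", [r.complemented() for r in out])
        a, _ = harmonize(small_table, out)
        b, _ = harmonize(small_table, comp)
        assert a == b

    def test_sign_involution_leaves_causal_estimate_unchanged(self, rng):
        """Flipping exposure rows (swap alleles, negate beta) negates the
        harmonized orientation but every Wald ratio — hence IVW — is invariant."""
        from conftest import study_scale_ses

        J = 12
        sx, sy = study_scale_ses(rng, J)
        gamma = rng.uniform(0.02, 0.05, J)
        exp_rows = [
            make_assoc(f"rs{i}", "A", "G", beta=float(gamma[i]), se=float(sx[i]))
            for i in range(J)
        ]
        out_rows = [
            make_assoc(f"rs{i}", "A", "G", beta=float(0.25 * gamma[i] + rng.normal(0, sy[i])), se=float(sy[i]))
            for i in range(J)
        ]
        exp, out = GwasTable("x", exp_rows), GwasTable("y", out_rows)
        flipped = GwasTable("x", [r.flipped() for r in exp_rows])
        a, _ = harmonize(exp, out)
        b, _ = harmonize(flipped, out)
        assert all(bi.beta_exposure == pytest.approx(-ai.beta_exposure) for ai, bi in zip(a, b))
        assert ivw(a, model="fixed").beta == pytest.approx(ivw(b, model="fixed").beta, rel=1e-12)

    def test_conservation_of_counts(self, rng):
        from tsmr.simulate import SyntheticConfig, generate

        data = generate(SyntheticConfig(n_snps=60, palindromic_fraction=0.1, seed=9))
        insts, report = harmonize(data.exposure, data.outcome)
        assert report.n_input == len(insts) + report.n_palindromic_dropped + report.n_unmatched_dropped

    def test_empty_exposure_rejected(self):
        with pytest.raises(GwasTableError):
            harmonize(GwasTable("x", []), GwasTable("y", [make_assoc()]))


class TestSubstituteProxy:
    @pytest.fixture
    def proxies(self, tmp_path):
        p = tmp_path / "proxies.tsv"
        p.write_text(
            "target_rsid\tproxy_rsid\tr2\tproxy_effect_allele_for_target_effect_allele\n"
            "rs_missing\trs_proxy1\t0.95\tT\n"
            "rs_missing\trs_proxy2\t0.92\tA\n"
            "rs_weak\trs_proxy3\t0.70\tA\n"
        )
        return read_proxy_table(p)

    def test_qualifying_proxy_substituted(self, proxies):
        outcome = GwasTable("y", [make_assoc("rs_proxy1", "T", "C", beta=0.04)])
        assoc = substitute_proxy("rs_missing", outcome, proxies)
        assert assoc is not None and assoc.rsid == "rs_proxy1"
        assert assoc.beta == pytest.approx(0.04)  # already oriented to T

    def test_sub_threshold_proxy_rejected(self, proxies):
        outcome = GwasTable("y", [make_assoc("rs_proxy3", "A", "G", beta=0.04)])
        assert substitute_proxy("rs_weak", outcome, proxies) is None

    def test_best_r2_proxy_preferred(self, proxies):
        outcome = GwasTable(
            "y",
            [make_assoc("rs_proxy1", "T", "C", beta=0.04), make_assoc("rs_proxy2", "A", "G", beta=0.02)],
        )
        assoc = substitute_proxy("rs_missing", outcome, proxies)
        assert assoc.rsid == "rs_proxy1"  # r2 0.95 beats 0.92

    def test_harmonize_records_proxy(self, proxies):
        exp = GwasTable("x", [make_assoc("rs_missing", "A", "G", beta=0.1)])
        outcome = GwasTable("y", [make_assoc("rs_proxy1", "T", "C", beta=0.04)])
        insts, report = harmonize(exp, outcome, proxies=proxies)
        assert len(insts) == 1
        assert insts[0].proxy_of == "rs_proxy1"
        assert insts[0].rsid == "rs_missing"
        assert report.n_proxied == 1
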