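import numpy as np
import pytest

from tsmr.summary_data import GwasTable, HarmonizedInstrument, SnpAssociation

# study-scale sample sizes used throughout the simulation tests
N_EXPOSURE = 321_223
N_OUTCOME = 1_030_836
CASE_FRACTION = 60_620 / 1_030_836


def make_instruments(bx, sx, by, sy, bm=None, sm=None):
    """HarmonizedInstrument list from parallel arrays."""
    out = []
    for i in range(len(bx)):
        out.append(
            HarmonizedInstrument(
                rsid=f"rs{i}",
                effect_allele="A",
                beta_exposure=float(bx[i]),
                se_exposure=float(sx[i]),
                beta_outcome=float(by[i]),
                se_outcome=float(sy[i]),
                beta_mediator=None if bm is None else float(bm[i]),
                se_mediator=None if sm is None else float(sm[i]),
            )
        )
    return out


def study_scale_ses(rng, n_snps):
    """Per-SNP SEs at the scale of the real exposure/outcome GWASs."""
    maf = rng.uniform(0.1, 0.5, n_snps)
    sx = 1.0 / np.sqrt(2 * maf * (1 - maf) * N_EXPOSURE)
    sy = 1.0 / np.sqrt(2 * maf * (1 - maf) * N_OUTCOME * CASE_FRACTION * (1 - CASE_FRACTION))
    return sx, sy


def random_instruments(rng, n_snps=30, beta=0.25, het_sd=0.0):
    """A clean random instrument set with true slope ``beta``."""
    sx, sy = study_scale_ses(rng, n_snps)
    gamma = rng.uniform(0.015, 0.06, n_snps) * rng.choice([-1.0, 1.0], n_snps)
    bx = gamma + rng.normal(0, sx)
    by = beta * gamma + rng.normal(0, sy)
    if het_sd > 0:
        by = by + rng.normal(0, het_sd, n_snps)
    return make_instruments(bx, sx, by, sy)


def make_assoc(rsid="rs1", ea="A", oa="G", beta=0.05, se=0.005, pvalue=1e-9, eaf=0.3, n=100_000):
    return SnpAssociation(
        rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se, pvalue=pvalue, eaf=eaf, n=n
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    return GwasTable(
        "exposure",
        [
            make_assoc("rs1", "A", "G", 0.05, 0.005, 1e-10),
            make_assoc("rs2", "T", "C", -0.03, 0.004, 1e-9),
            make_assoc("rs3", "G", "A", 0.02, 0.006, 2e-3),
        ],
    )
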