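import numpy as np
import pytest

from mrpath import HarmonizedInstruments, SnpAssociation


def make_h(beta_exp, se_exp, beta_out, se_out, eaf=None):
    """Build a HarmonizedInstruments from parallel effect lists."""
    j = len(beta_exp)
    if eaf is None:
        eaf = [0.3] * j
    return HarmonizedInstruments(
        snp_ids=[f"s{i}" for i in range(j)],
        beta_exp=beta_exp, se_exp=se_exp,
        beta_out=beta_out, se_out=se_out, eaf=eaf,
    )


def make_snp(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
             beta=0.1, se=0.02, pval=1e-8, n=10000):
    return SnpAssociation(snp_id=snp_id, chrom=chrom, pos=pos,
                          effect_allele=ea, other_allele=oa, eaf=eaf,
                          beta=beta, se=se, pval=pval, n=n)


def strong_null_instruments(rng, j=50, theta=0.0, gamma_sd=0.3,
                            n_exp=7738, n_out=20000):
    """Strong-instrument set with homogeneous (no-pleiotropy) outcome
    effects theta * gamma_j; theta=0 gives the heterogeneity null."""
    maf = rng.uniform(0.1, 0.4, j)
    se_e = 1 / np.sqrt(2 * maf * (1 - maf) * n_exp)
    se_o = 2 / np.sqrt(2 * maf * (1 - maf) * n_out)  # balanced binary outcome
    gamma = rng.normal(0, gamma_sd, j)
    beta_exp = gamma + rng.normal(0, se_e)
    beta_out = theta * gamma + rng.normal(0, se_o)
    return make_h(beta_exp, se_e, beta_out, se_o, eaf=maf)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def exact_linear_h():
    """beta_out = 0.01 + 0.5 * beta_exp exactly, positive exposure effects."""
    bx = np.array([0.1, 0.2, 0.3, 0.4])
    return make_h(bx, [0.01] * 4, 0.01 + 0.5 * bx, [0.02] * 4)
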