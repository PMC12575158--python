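"""Synthetic GWAS summary statistics with known causal structure.

The generator emulates the data shape of a microbiome-style mediation MR
study: an exposure trait instrumented by a modest number of
genome-wide-suggestive variants, a mediator trait, and a rare binary
outcome on the log-odds scale, with optional directional pleiotropy,
excess heterogeneity, and block-wise LD for clumping tests.

Simulation is at summary level — no individual genotypes. For each variant
the per-trait sampling SE follows the standard GWAS approximation
``se = 1 / sqrt(2 maf (1 - maf) n)`` for a variance-standardized trait;
binary-outcome SEs are additionally inflated by ``1/sqrt(phi (1 - phi))``
with ``phi`` the case fraction, which on the log-odds scale reproduces the
very wide intervals a 69-case outcome produces. Observed effects are the
true effects plus normal noise at the per-variant SE.

Causal structure (per exposure-instrument variant j with true effect
gamma_j ~ N(0, gamma_sd^2)):

* exposure truth: gamma_j
* mediator truth: beta1 * gamma_j + alpha_j^med   (pleiotropy to mediator)
* outcome truth:  (direct + beta1*beta2) * gamma_j + alpha_j
  with alpha_j ~ N(pleio_mean, pleio_sd^2)

A second panel of mediator-specific instruments (delta_j ~ N(0,
delta_sd^2), outcome truth beta2 * delta_j, zero exposure effect) is
generated so Step 2 of the mediation analysis has instruments for the
mediator that are independent of the exposure; without such a panel the
ratio at exposure variants identifies (direct + beta1*beta2)/beta1, not
beta2.

Default configuration mirrors the paper-like design: 12 instruments,
exposure n = 7,738, mediator n = 8,299, outcome n = 345,187 with 69 cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .instruments import LdMatrix
from .sumstats import SnpAssociation

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]  # non-palindromic


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the paper-like scenario
    (microbiome exposure, metabolite mediator, rare binary outcome)."""

    n_snp: int = 12
    n_snp_med: int | None = None  # defaults to n_snp
    n_exp: int = 7_738
    n_med: int = 8_299
    n_out: int = 345_187
    n_cases: int | None = 69
    maf_range: tuple = (0.05, 0.5)
    gamma_sd: float = 0.15
    delta_sd: float | None = None  # defaults to gamma_sd
    beta1: float = 0.0
    beta2: float = 0.0
    direct: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    ld_block_size: int = 1
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")
        for nm in ("n_exp", "n_med", "n_out"):
            if getattr(self, nm) < 4:
                raise ValueError(f"{nm} must be >= 4")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_cases is not None and not (0 < self.n_cases < self.n_out):
            raise ValueError("n_cases must be in (0, n_out)")
        if not (abs(self.ld_rho) < 1):
            raise ValueError("|ld_rho| must be < 1")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.gamma_sd < 0 or self.pleio_sd < 0:
            raise ValueError("spread parameters must be non-negative")

    @property
    def n_snp_mediator(self) -> int:
        return self.n_snp if self.n_snp_med is None else self.n_snp_med

    @property
    def delta_spread(self) -> float:
        return self.gamma_sd if self.delta_sd is None else self.delta_sd

    @property
    def beta_all(self) -> float:
        """True total exposure -> outcome effect, direct + beta1*beta2."""
        return self.direct + self.beta1 * self.beta2


@dataclass
class TruthRecord:
    """Realized simulation ground truth; bit-reproducible from the config."""

    config: SimConfig
    gamma: np.ndarray          # exposure-instrument effects on exposure
    alpha_out: np.ndarray      # pleiotropic effects on outcome
    alpha_med: np.ndarray      # pleiotropic effects on mediator
    delta: np.ndarray          # mediator-instrument effects on mediator
    exposure_snp_ids: list[str] = field(default_factory=list)
    mediator_snp_ids: list[str] = field(default_factory=list)

    @property
    def beta_all(self) -> float:
        return self.config.beta_all


def _positions(n: int, block: int) -> np.ndarray:
    """Block b sits 20,000 kb from its neighbours (beyond any clumping
    window used here); variants within a block are 1 kb apart."""
    idx = np.arange(n)
    return (1_000_000 + (idx // block) * 20_000_000 + (idx % block) * 1_000).astype(int)


def _records(ids, chrom, pos, maf, truth, se, n, rng) -> list[SnpAssociation]:
    beta_obs = truth + rng.standard_normal(len(ids)) * se
    pvals = np.clip(2 * stats.norm.sf(np.abs(beta_obs / se)), 1e-300, 1.0)
    out = []
    for k, sid in enumerate(ids):
        ea, oa = _ALLELE_PAIRS[k % len(_ALLELE_PAIRS)]
        out.append(SnpAssociation(
            snp_id=sid, chrom=chrom, pos=int(pos[k]),
            effect_allele=ea, other_allele=oa, eaf=float(maf[k]),
            beta=float(beta_obs[k]), se=float(se[k]),
            pval=float(pvals[k]), n=n,
        ))
    return out


def simulate_triplet(cfg: SimConfig):
    """Generate (exposure_stats, mediator_stats, outcome_stats, truth).

    Each stats list covers *all* simulated variants (exposure panel on
    chromosome 1, mediator panel on chromosome 2), so instrument selection
    against any of the three traits behaves as it would on real
    genome-wide tables.
    """
    rng = np.random.default_rng(cfg.seed)
    n_e, n_m = cfg.n_snp, cfg.n_snp_mediator
    lo, hi = cfg.maf_range

    exp_ids = [f"rs{1000 + k}" for k in range(n_e)]
    med_ids = [f"rs{5000 + k}" for k in range(n_m)]
    pos_e = _positions(n_e, cfg.ld_block_size)
    pos_m = _positions(n_m, cfg.ld_block_size)
    maf_e = rng.uniform(lo, hi, n_e)
    maf_m = rng.uniform(lo, hi, n_m)

    gamma = rng.normal(0.0, cfg.gamma_sd, n_e)
    alpha_out = rng.normal(cfg.pleio_mean, cfg.pleio_sd, n_e) if cfg.pleio_sd > 0 or cfg.pleio_mean != 0 else np.zeros(n_e)
    alpha_med = rng.normal(cfg.pleio_mean, cfg.pleio_sd, n_e) if cfg.pleio_sd > 0 or cfg.pleio_mean != 0 else np.zeros(n_e)
    delta = rng.normal(0.0, cfg.delta_spread, n_m)

    def se_for(maf, n, binary_cases=None):
        se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n)
        if binary_cases is not None:
            phi = binary_cases / n
            se = se / np.sqrt(phi * (1 - phi))
        return se

    se_exp_e, se_exp_m = se_for(maf_e, cfg.n_exp), se_for(maf_m, cfg.n_exp)
    se_med_e, se_med_m = se_for(maf_e, cfg.n_med), se_for(maf_m, cfg.n_med)
    se_out_e = se_for(maf_e, cfg.n_out, cfg.n_cases)
    se_out_m = se_for(maf_m, cfg.n_out, cfg.n_cases)

    truth_exp_e = gamma
    truth_exp_m = np.zeros(n_m)
    truth_med_e = cfg.beta1 * gamma + alpha_med
    truth_med_m = delta
    truth_out_e = cfg.beta_all * gamma + alpha_out
    truth_out_m = cfg.beta2 * delta

    exposure = (_records(exp_ids, "1", pos_e, maf_e, truth_exp_e, se_exp_e, cfg.n_exp, rng)
                + _records(med_ids, "2", pos_m, maf_m, truth_exp_m, se_exp_m, cfg.n_exp, rng))
    mediator = (_records(exp_ids, "1", pos_e, maf_e, truth_med_e, se_med_e, cfg.n_med, rng)
                + _records(med_ids, "2", pos_m, maf_m, truth_med_m, se_med_m, cfg.n_med, rng))
    outcome = (_records(exp_ids, "1", pos_e, maf_e, truth_out_e, se_out_e, cfg.n_out, rng)
               + _records(med_ids, "2", pos_m, maf_m, truth_out_m, se_out_m, cfg.n_out, rng))

    truth = TruthRecord(config=cfg, gamma=gamma, alpha_out=alpha_out,
                        alpha_med=alpha_med, delta=delta,
                        exposure_snp_ids=exp_ids, mediator_snp_ids=med_ids)
    return exposure, mediator, outcome, truth


def _block_ar1(n: int, block: int, rho: float) -> np.ndarray:
    r2 = np.zeros((n, n))
    for start in range(0, n, block):
        stop = min(start + block, n)
        idx = np.arange(start, stop)
        lag = np.abs(idx[:, None] - idx[None, :])
        r2[start:stop, start:stop] = rho ** (2 * lag)
    np.fill_diagonal(r2, 1.0)
    return r2


def simulate_ld(cfg: SimConfig) -> LdMatrix:
    """Block-diagonal AR(1) LD over all simulated variants: within a block
    r^2(i, j) = ld_rho^(2|i-j|), zero across blocks and across the two
    panels. Positions (see :func:`simulate_triplet`) keep each block well
    inside a clumping window and distinct blocks far outside it."""
    n_e, n_m = cfg.n_snp, cfg.n_snp_mediator
    ids = [f"rs{1000 + k}" for k in range(n_e)] + [f"rs{5000 + k}" for k in range(n_m)]
    r2 = np.zeros((n_e + n_m, n_e + n_m))
    r2[:n_e, :n_e] = _block_ar1(n_e, cfg.ld_block_size, cfg.ld_rho)
    r2[n_e:, n_e:] = _block_ar1(n_m, cfg.ld_block_size, cfg.ld_rho)
    return LdMatrix(snp_ids=ids, r2=r2)
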