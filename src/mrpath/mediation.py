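"""Two-step MR mediation with effect decomposition.

Step 1 estimates the exposure -> mediator effect beta1 by univariable MR
(IVW, random-effects default) using the exposure's instruments; a
significance gate (default p < 0.05) decides whether the path proceeds.
Step 2 treats the mediator as the exposure and estimates the mediator ->
outcome effect beta2 with the *mediator's own* instruments. The indirect
effect is the product beta1 * beta2; its uncertainty comes from the delta
method, se = sqrt(beta1^2 se2^2 + beta2^2 se1^2) (first-order; an
exact-product option adds the se1^2 se2^2 cross-term), or from a seeded
parametric bootstrap drawing (beta1*, beta2*) independently — sampling
errors of the two steps are taken as independent because they come from
distinct GWAS samples.

The mediation proportion is indirect / total, where the total effect
beta_all is the direct univariable MR estimate of exposure on outcome.
When indirect and total disagree in sign the signed proportion is reported
with ``consistent_signs=False`` — inconsistent mediation is surfaced, not
masked, because a mediator that opposes the total effect cannot explain it.
Note beta2 is a univariable estimate (no adjustment for the exposure), so
the decomposition is exact only when the mediator's instruments do not act
on the outcome through the exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import MREstimate, Z95, ivw, wald_ratio
from .exceptions import UndefinedProportionError
from .sumstats import HarmonizedInstruments


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: 1000 repetitions by default, percentile CIs."""

    n_boot: int = 1000
    seed: int = 0
    ci_method: str = "percentile"  # {percentile, normal}

    def __post_init__(self):
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if self.ci_method not in ("percentile", "normal"):
            raise ValueError("ci_method must be percentile|normal")


@dataclass
class MediationEstimate:
    """Decomposition of one exposure -> mediator -> outcome path."""

    beta1: float
    se1: float
    beta2: float | None
    se2: float | None
    indirect: float | None
    indirect_se: float | None
    indirect_ci_low: float | None
    indirect_ci_high: float | None
    total: float | None
    total_se: float | None
    proportion: float | None
    consistent_signs: bool | None
    gate_passed: bool
    gate_p: float
    est1: MREstimate | None = None
    est2: MREstimate | None = None
    est_total: MREstimate | None = None


def indirect_effect(beta1: float, se1: float, beta2: float, se2: float,
                    method: str = "delta", cfg: BootstrapConfig | None = None,
                    exact_product: bool = False):
    """Indirect effect beta1*beta2 with SE and 95% CI.

    ``method="delta"``: se = sqrt(beta1^2 se2^2 + beta2^2 se1^2), plus the
    se1^2 se2^2 cross-term when ``exact_product``; CI = indirect +/- 1.96 se.
    ``method="bootstrap"``: draw (beta1*, beta2*) independently from
    normal(beta_i, se_i); CI per ``cfg.ci_method``; seeded.

    Returns ``(indirect, se, (ci_low, ci_high))``.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    indirect = beta1 * beta2
    if method == "delta":
        var = beta1 ** 2 * se2 ** 2 + beta2 ** 2 * se1 ** 2
        if exact_product:
            var += se1 ** 2 * se2 ** 2
        se = float(np.sqrt(var))
        return indirect, se, (indirect - Z95 * se, indirect + Z95 * se)
    if method != "bootstrap":
        raise ValueError("method must be delta|bootstrap")
    cfg = cfg or BootstrapConfig()
    rng = np.random.default_rng(cfg.seed)
    draws = rng.normal(beta1, se1, cfg.n_boot) * rng.normal(beta2, se2, cfg.n_boot)
    se = float(np.std(draws, ddof=1))
    if cfg.ci_method == "percentile":
        lo, hi = np.percentile(draws, [2.5, 97.5])
    else:
        lo, hi = indirect - Z95 * se, indirect + Z95 * se
    return indirect, se, (float(lo), float(hi))


def mediation_proportion(indirect: float, total: float) -> tuple[float, bool]:
    """Signed mediation proportion indirect/total and a sign-consistency
    flag (False when indirect and total point in opposite directions)."""
    if total == 0:
        raise UndefinedProportionError("mediation proportion undefined for zero total effect")
    prop = indirect / total
    consistent = indirect == 0 or (indirect > 0) == (total > 0)
    return float(prop), bool(consistent)


def proportion_ci(beta1: float, se1: float, beta2: float, se2: float,
                  total: float, total_se: float,
                  cfg: BootstrapConfig | None = None) -> tuple[float, float]:
    """Percentile bootstrap CI for the mediation proportion, drawing the
    three component estimates independently (distinct GWAS samples)."""
    cfg = cfg or BootstrapConfig()
    rng = np.random.default_rng(cfg.seed)
    ind = rng.normal(beta1, se1, cfg.n_boot) * rng.normal(beta2, se2, cfg.n_boot)
    tot = rng.normal(total, total_se, cfg.n_boot)
    lo, hi = np.percentile(ind / tot, [2.5, 97.5])
    return float(lo), float(hi)


def _univariable_ivw(h: HarmonizedInstruments) -> MREstimate:
    if h.n_snp >= 2:
        return ivw(h, model="random")
    return wald_ratio(h.beta_exp[0], h.se_exp[0], h.beta_out[0], h.se_out[0])


def two_step_mediation(exp_med: HarmonizedInstruments,
                       med_out: HarmonizedInstruments,
                       exp_out: HarmonizedInstruments,
                       cfg: BootstrapConfig | None = None,
                       method: str = "delta",
                       gate_alpha: float = 0.05,
                       gate: bool = True) -> MediationEstimate:
    """Run the two-step procedure on three harmonized instrument sets.

    ``exp_med``: exposure instruments vs mediator (Step 1, beta1);
    ``med_out``: mediator instruments vs outcome (Step 2, beta2);
    ``exp_out``: exposure instruments vs outcome (total effect beta_all).
    Each estimate is univariable IVW (random-effects when J >= 2). When the
    Step-1 gate fails (p >= gate_alpha), an explicit not-mediated result is
    returned carrying the gating p — not an exception.
    """
    cfg = cfg or BootstrapConfig()
    est1 = _univariable_ivw(exp_med)
    if gate and est1.pval >= gate_alpha:
        return MediationEstimate(
            beta1=est1.beta, se1=est1.se, beta2=None, se2=None,
            indirect=None, indirect_se=None,
            indirect_ci_low=None, indirect_ci_high=None,
            total=None, total_se=None, proportion=None,
            consistent_signs=None, gate_passed=False, gate_p=est1.pval,
            est1=est1,
        )
    est2 = _univariable_ivw(med_out)
    est_total = _univariable_ivw(exp_out)
    ind, ind_se, (lo, hi) = indirect_effect(
        est1.beta, est1.se, est2.beta, est2.se, method=method, cfg=cfg)
    prop, consistent = mediation_proportion(ind, est_total.beta)
    return MediationEstimate(
        beta1=est1.beta, se1=est1.se, beta2=est2.beta, se2=est2.se,
        indirect=ind, indirect_se=ind_se,
        indirect_ci_low=float(lo), indirect_ci_high=float(hi),
        total=est_total.beta, total_se=est_total.se,
        proportion=prop, consistent_signs=consistent,
        gate_passed=True, gate_p=est1.pval,
        est1=est1, est2=est2, est_total=est_total,
    )
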