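"""Causal-effect estimators for two-sample MR.

Given J harmonized instruments with exposure effects ``beta_exp_j`` (SE
``se_exp_j``) and outcome effects ``beta_out_j`` (SE ``se_out_j``), each
instrument yields a Wald ratio ``theta_j = beta_out_j / beta_exp_j``. The
estimators pool these ratios under different validity assumptions:

``ivw``
    Inverse-variance weighted mean of the ratios (equivalently, the
    zero-intercept WLS slope of outcome on exposure effects with weights
    1/se_out^2). Assumes all instruments valid. The random-effects variant
    (the default in screening) inflates the fixed-effects SE by
    sqrt(Q / (J - 1)) floored at 1 — a multiplicative overdispersion model
    that widens the interval under heterogeneity but never narrows it.
``egger``
    WLS of outcome on exposure effects *with* a free intercept. The
    intercept estimates the average directional pleiotropic effect; the
    slope is a pleiotropy-corrected causal estimate under the InSIDE
    assumption (instrument strength independent of direct effects).
    Exposure effects are reoriented non-negative before fitting.
``weighted_median``
    Weighted median of the ratios; consistent when instruments carrying
    more than half the weight are valid. SE by parametric bootstrap.
``mode_estimate``
    Mode of a normal-kernel density over the ratios (simple = uniform
    weights, weighted = inverse-variance weights); consistent when the
    largest cluster of instruments is valid. SE by parametric bootstrap.

Ratio variances use the first-order approximation var(theta_j) ~
se_out_j^2 / beta_exp_j^2, ignoring exposure-side noise (adequate for
strong instruments); ``second_order=True`` adds the
theta_j^2 se_exp_j^2 / beta_exp_j^2 term.

Binary outcomes are on the log-odds scale, so every estimate carries its
exponentiated triple: OR = exp(beta) with 95% bounds exp(beta +/- 1.96 se).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientInstrumentsError, UndefinedRatioError
from .sumstats import HarmonizedInstruments

Z95 = 1.959963984540054  # standard normal 97.5% quantile

_MIN_SNPS = {
    "wald_ratio": 1, "ivw_fe": 1, "ivw_re": 2, "egger_slope": 3,
    "weighted_median": 3, "simple_mode": 3, "weighted_mode": 3,
}


@dataclass(frozen=True)
class MREstimate:
    """One method's causal-effect estimate with OR/CI/p."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    or_value: float
    or_low: float
    or_high: float
    pval: float
    n_snp: int

    def __post_init__(self):
        if self.method not in _MIN_SNPS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_snp < _MIN_SNPS[self.method]:
            raise ValueError(f"{self.method} requires >= {_MIN_SNPS[self.method]} instruments")


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect: (OR, lower, upper) with 95% bounds
    exp(beta +/- 1.96 se)."""
    if se < 0:
        raise ValueError("se must be non-negative")
    with np.errstate(over="ignore"):  # huge-SE bounds saturate to inf
        return (float(np.exp(beta)),
                float(np.exp(beta - Z95 * se)),
                float(np.exp(beta + Z95 * se)))


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2 * stats.norm.sf(abs(beta) / se))


def _make(method: str, beta: float, se: float, n_snp: int, pval: float | None = None) -> MREstimate:
    or_v, or_lo, or_hi = to_odds_ratio(beta, se)
    return MREstimate(
        method=method, beta=float(beta), se=float(se),
        ci_low=float(beta - Z95 * se), ci_high=float(beta + Z95 * se),
        or_value=or_v, or_low=or_lo, or_high=or_hi,
        pval=float(pval) if pval is not None else _normal_p(beta, se),
        n_snp=int(n_snp),
    )


def ratio_estimates(h: HarmonizedInstruments, second_order: bool = False):
    """Per-instrument Wald ratios and their (approximate) variances."""
    if np.any(h.beta_exp == 0):
        raise UndefinedRatioError("zero exposure effect among instruments")
    theta = h.beta_out / h.beta_exp
    var = h.se_out ** 2 / h.beta_exp ** 2
    if second_order:
        var = var + theta ** 2 * h.se_exp ** 2 / h.beta_exp ** 2
    return theta, var


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp with
    first-order SE se_out / |beta_exp|."""
    if beta_exp == 0:
        raise UndefinedRatioError("wald ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return _make("wald_ratio", beta, se, 1)


def ivw(h: HarmonizedInstruments, model: str = "random") -> MREstimate:
    """Inverse-variance weighted estimate.

    With weights w_j = beta_exp_j^2 / se_out_j^2 the point estimate is
    sum(beta_exp_j beta_out_j / se_out_j^2) / sum(beta_exp_j^2 / se_out_j^2)
    and the fixed-effects SE is 1/sqrt(sum w_j). ``model="random"``
    (requires J >= 2) multiplies the SE by max(1, sqrt(Q/(J-1))).
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    j = h.n_snp
    if j < 1:
        raise InsufficientInstrumentsError("IVW requires at least one instrument")
    if model == "random" and j < 2:
        raise InsufficientInstrumentsError("random-effects IVW requires J >= 2")
    if np.any(h.beta_exp == 0):
        raise UndefinedRatioError("zero exposure effect among instruments")
    w = h.beta_exp ** 2 / h.se_out ** 2
    beta = float(np.sum(h.beta_exp * h.beta_out / h.se_out ** 2) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    method = "ivw_fe"
    if model == "random":
        theta = h.beta_out / h.beta_exp
        q = float(np.sum(w * (theta - beta) ** 2))
        se *= max(1.0, np.sqrt(q / (j - 1)))
        method = "ivw_re"
    return _make(method, beta, se, j)


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger fit: pleiotropy-corrected slope plus the intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float


def egger(h: HarmonizedInstruments, orient_exposure: bool = True) -> EggerResult:
    """MR-Egger weighted regression of outcome on exposure effects.

    Weights 1/se_out_j^2; exposure effects reoriented non-negative by
    default (the pair (beta_exp_j, beta_out_j) is sign-flipped when
    beta_exp_j < 0). Coefficient SEs are the unscaled WLS SEs multiplied by
    max(1, residual standard error); p-values from t with J-2 df.
    """
    j = h.n_snp
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger requires J >= 3")
    bx, by = h.beta_exp.copy(), h.beta_out.copy()
    if orient_exposure:
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
    w = 1.0 / h.se_out ** 2
    x = np.column_stack([np.ones(j), bx])
    a = x.T @ (w[:, None] * x)
    coef = np.linalg.solve(a, x.T @ (w * by))
    resid = by - x @ coef
    sigma2 = float(np.sum(w * resid ** 2) / (j - 2))
    cov_unscaled = np.linalg.inv(a)
    scale = max(1.0, np.sqrt(sigma2))
    se = np.sqrt(np.diag(cov_unscaled)) * scale
    tvals = coef / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=j - 2)
    slope = _make("egger_slope", coef[1], se[1], j, pval=pvals[1])
    return EggerResult(slope=slope, intercept=float(coef[0]),
                       intercept_se=float(se[0]), intercept_p=float(pvals[0]))


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    th, wt = theta[order], w[order] / np.sum(w)
    s = np.cumsum(wt) - wt / 2  # cumulative midpoints
    if 0.5 <= s[0]:
        return float(th[0])
    if 0.5 >= s[-1]:
        return float(th[-1])
    return float(np.interp(0.5, s, th))


def _parametric_boot(h: HarmonizedInstruments, point_fn, n_boot: int, seed,
                     robust: bool = False) -> float:
    """Bootstrap SE: resample (beta_exp_j, beta_out_j) from normal(observed,
    se) and recompute the point estimate. ``robust=True`` uses the
    normal-scaled MAD of the bootstrap distribution instead of its SD —
    the usual choice for the mode estimator, whose bootstrap distribution
    has occasional far-off modes that inflate the SD."""
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(h.beta_exp, h.se_exp)
        by = rng.normal(h.beta_out, h.se_out)
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)
        ests[b] = point_fn(by / bx, bx)
    if robust:
        return float(stats.median_abs_deviation(ests, scale="normal"))
    return float(np.std(ests, ddof=1))


def weighted_median(h: HarmonizedInstruments, n_boot: int = 1000, *, seed) -> MREstimate:
    """Weighted median of the Wald ratios; inverse-variance (first-order)
    weights; SE by seeded parametric bootstrap."""
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("weighted median requires J >= 3")
    theta, var = ratio_estimates(h)
    w = 1.0 / var
    beta = _weighted_median_point(theta, w)

    def point(th, bx):
        return _weighted_median_point(th, bx ** 2 / h.se_out ** 2)

    se = _parametric_boot(h, point, n_boot, seed)
    return _make("weighted_median", beta, se, h.n_snp)


def _kde_mode(theta: np.ndarray, w: np.ndarray, bandwidth_factor: float) -> float:
    """Argmax of a normal-kernel weighted density over the ratios, on a
    512-point grid spanning [min - 3h, max + 3h]."""
    j = len(theta)
    sd = float(np.std(theta, ddof=1))
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    h_bw = bandwidth_factor * 0.9 * min(sd, iqr / 1.349) * j ** (-1 / 5)
    if h_bw <= 0:  # all ratios identical (or IQR zero with sd zero)
        return float(theta[0]) if sd == 0 else float(np.median(theta))
    grid = np.linspace(theta.min() - 3 * h_bw, theta.max() + 3 * h_bw, 512)
    wn = w / np.sum(w)
    dens = np.sum(wn[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h_bw) ** 2), axis=1)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(h: HarmonizedInstruments, weighted: bool = False,
                  bandwidth_factor: float = 1.0, n_boot: int = 1000, *, seed) -> MREstimate:
    """Mode-based estimate: argmax of the kernel-smoothed ratio density.

    ``weighted=False`` uses uniform kernel weights (simple mode);
    ``weighted=True`` uses inverse-variance weights. Bandwidth
    h = phi * 0.9 * min(sd, iqr/1.349) * J^(-1/5). All-identical ratios
    short-circuit to the common ratio. SE by seeded parametric bootstrap.
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("mode estimator requires J >= 3")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    theta, var = ratio_estimates(h)
    w = (1.0 / var) if weighted else np.ones_like(theta)
    beta = _kde_mode(theta, w, bandwidth_factor)

    def point(th, bx):
        wt = (bx ** 2 / h.se_out ** 2) if weighted else np.ones_like(th)
        return _kde_mode(th, wt, bandwidth_factor)

    se = _parametric_boot(h, point, n_boot, seed, robust=True)
    return _make("weighted_mode" if weighted else "simple_mode", beta, se, h.n_snp)


def all_estimates(h: HarmonizedInstruments, *, seed, n_boot: int = 1000) -> list[MREstimate]:
    """Every estimator the instrument count supports, in a fixed order:
    IVW (random-effects when J >= 2, else Wald ratio), then for J >= 3
    Egger slope, weighted median, simple and weighted mode."""
    out: list[MREstimate] = []
    if h.n_snp == 1:
        out.append(wald_ratio(h.beta_exp[0], h.se_exp[0], h.beta_out[0], h.se_out[0]))
        return out
    out.append(ivw(h, model="random"))
    if h.n_snp >= 3:
        out.append(egger(h).slope)
        out.append(weighted_median(h, n_boot=n_boot, seed=seed))
        out.append(mode_estimate(h, weighted=False, n_boot=n_boot, seed=seed + 1))
        out.append(mode_estimate(h, weighted=True, n_boot=n_boot, seed=seed + 2))
    return out
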