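"""Sensitivity battery for two-sample MR.

Four procedures probe the instrument-validity assumptions:

* **Cochran's Q** — heterogeneity of the per-instrument Wald ratios around
  the pooled estimate; Q ~ chi^2(J - df_loss) under homogeneity (df_loss 1
  for IVW, 2 for the Egger fit, whose Q uses residuals from the intercept
  model). Significant Q motivates the random-effects IVW model.
* **MR-Egger intercept** — a non-zero intercept indicates directional
  pleiotropy (computed in :mod:`mrpath.estimators`, surfaced here).
* **MR-PRESSO** — simulation-based residual-sum-of-squares test: the
  observed weighted RSS around leave-one-out IVW predictions is compared
  with its parametric-null distribution; per-instrument contributions flag
  pleiotropic outliers (Bonferroni across the J instruments).
* **MR-Steiger** — directionality check: instruments should explain more
  variance in the exposure than in the outcome. Variance explained per
  instrument is the z-based pseudo-r^2, z^2/(z^2 + n - 2), applied
  uniformly to both traits (an approximation on the binary-outcome
  log-odds scale); the aggregate correlations are compared with a
  two-sample Fisher z test.

Monte-Carlo p-values use add-one smoothing, (1 + k)/(1 + n_sim), so a
reported p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EggerResult, MREstimate
from .exceptions import InsufficientInstrumentsError
from .sumstats import HarmonizedInstruments


def cochran_q(h: HarmonizedInstruments, beta_hat: float, df_loss: int = 1,
              intercept: float = 0.0) -> tuple[float, int, float]:
    """Cochran's Q statistic and chi-square tail p-value.

    Q = sum_j w_j (theta_j - beta_hat)^2 with w_j = beta_exp_j^2/se_out_j^2
    and theta_j the per-instrument ratio; equivalently (and as implemented)
    the weighted residual sum of squares in outcome-effect space, which for
    ``df_loss=2`` accommodates the Egger intercept: residuals are
    beta_out_j - intercept - beta_hat * beta_exp_j.
    """
    if df_loss not in (1, 2):
        raise ValueError("df_loss must be 1 (IVW) or 2 (Egger)")
    j = h.n_snp
    if j <= df_loss:
        raise InsufficientInstrumentsError(f"Q undefined: J={j} <= df_loss={df_loss}")
    resid = h.beta_out - intercept - beta_hat * h.beta_exp
    q = float(np.sum(resid ** 2 / h.se_out ** 2))
    df = j - df_loss
    p = float(stats.chi2.sf(q, df))
    return q, df, p


@dataclass(frozen=True)
class PressoResult:
    global_p: float
    outlier_ids: list[str]
    outlier_pvals: dict[str, float]
    rss_obs: float


def presso_test(h: HarmonizedInstruments, n_sim: int = 5000, *, seed,
                outlier_alpha: float = 0.05) -> PressoResult:
    """MR-PRESSO global test and outlier flagging.

    The observed statistic is RSS_obs = sum_j (beta_out_j -
    theta_(-j) beta_exp_j)^2 / se_out_j^2 with theta_(-j) the leave-one-out
    IVW estimate. The null distribution is built by drawing
    beta_out_j* ~ N(theta_(-j) beta_exp_j, se_out_j) and recomputing the
    statistic (leave-one-out estimates re-fitted on the simulated data).
    Per-instrument contributions yield outlier p-values, flagged below
    ``outlier_alpha / J`` (Bonferroni). Seeded and fully reproducible.
    """
    j = h.n_snp
    if j < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires J >= 4")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    be, bo, so = h.beta_exp, h.beta_out, h.se_out
    w = 1.0 / so ** 2
    num = be * bo * w
    den = be ** 2 * w
    theta_loo = (np.sum(num) - num) / (np.sum(den) - den)
    pred = theta_loo * be
    contrib_obs = w * (bo - pred) ** 2
    rss_obs = float(np.sum(contrib_obs))

    bo_star = pred[None, :] + rng.standard_normal((n_sim, j)) * so[None, :]
    num_s = be[None, :] * bo_star * w[None, :]
    theta_loo_s = (num_s.sum(axis=1, keepdims=True) - num_s) / (np.sum(den) - den)[None, :]
    contrib_s = w[None, :] * (bo_star - theta_loo_s * be[None, :]) ** 2
    rss_s = contrib_s.sum(axis=1)

    global_p = float((1 + np.sum(rss_s >= rss_obs)) / (n_sim + 1))
    p_snp = (1 + np.sum(contrib_s >= contrib_obs[None, :], axis=0)) / (n_sim + 1)
    cut = outlier_alpha / j
    outliers = [h.snp_ids[k] for k in range(j) if p_snp[k] < cut]
    return PressoResult(
        global_p=global_p, outlier_ids=outliers,
        outlier_pvals={h.snp_ids[k]: float(p_snp[k]) for k in range(j)},
        rss_obs=rss_obs,
    )


@dataclass(frozen=True)
class SteigerResult:
    r2_exp: float
    r2_out: float
    direction: bool
    pval: float


def steiger_test(h: HarmonizedInstruments, n_exp: int, n_out: int) -> SteigerResult:
    """MR-Steiger directionality test.

    Per-instrument variance explained is the z-based pseudo-r^2,
    r2_j = z_j^2 / (z_j^2 + n - 2), summed over instruments for each trait.
    ``direction`` is True when the instruments explain strictly more
    variance in the exposure than in the outcome; the p-value comes from a
    two-sample Fisher z test comparing the aggregate correlations
    sqrt(sum r2) at the two sample sizes.
    """
    if n_exp < 4 or n_out < 4:
        raise ValueError("Steiger test requires n >= 4 for both traits")
    z_exp = h.beta_exp / h.se_exp
    z_out = h.beta_out / h.se_out
    r2_exp = float(np.sum(z_exp ** 2 / (z_exp ** 2 + n_exp - 2)))
    r2_out = float(np.sum(z_out ** 2 / (z_out ** 2 + n_out - 2)))
    r_exp = np.sqrt(min(r2_exp, 1.0 - 1e-12))
    r_out = np.sqrt(min(r2_out, 1.0 - 1e-12))
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(1 / (n_exp - 3) + 1 / (n_out - 3))
    p = float(2 * stats.norm.sf(abs(z)))
    return SteigerResult(r2_exp=r2_exp, r2_out=r2_out,
                         direction=r2_exp > r2_out, pval=p)


@dataclass
class SensitivityReport:
    """Aggregated sensitivity results for one exposure-outcome pair."""

    q_ivw: float
    q_ivw_p: float
    q_egger: float
    q_egger_p: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    presso_global_p: float | None
    presso_outliers: list[str]
    steiger_direction: bool
    steiger_p: float
    heterogeneity_flag: bool = False
    pleiotropy_flag: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "Q_IVW": self.q_ivw, "Pval_Q_IVW": self.q_ivw_p,
            "Q_Egger": self.q_egger, "Pval_Q_Egger": self.q_egger_p,
            "Egger_intercept": self.egger_intercept,
            "Egger_intercept_SE": self.egger_intercept_se,
            "Pval_Egger_intercept": self.egger_intercept_p,
            "PRESSO_global_p": self.presso_global_p,
            "PRESSO_outliers": ",".join(self.presso_outliers),
            "Steiger": self.steiger_direction, "Pval_Steiger": self.steiger_p,
            "heterogeneity_flag": self.heterogeneity_flag,
            "pleiotropy_flag": self.pleiotropy_flag,
        }])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SensitivityReport":
        row = pd.read_csv(path, sep="\t").iloc[0]
        outliers = [] if pd.isna(row["PRESSO_outliers"]) or row["PRESSO_outliers"] == "" \
            else str(row["PRESSO_outliers"]).split(",")
        presso_p = None if pd.isna(row["PRESSO_global_p"]) else float(row["PRESSO_global_p"])
        return cls(
            q_ivw=float(row["Q_IVW"]), q_ivw_p=float(row["Pval_Q_IVW"]),
            q_egger=float(row["Q_Egger"]), q_egger_p=float(row["Pval_Q_Egger"]),
            egger_intercept=float(row["Egger_intercept"]),
            egger_intercept_se=float(row["Egger_intercept_SE"]),
            egger_intercept_p=float(row["Pval_Egger_intercept"]),
            presso_global_p=presso_p, presso_outliers=outliers,
            steiger_direction=bool(row["Steiger"]), steiger_p=float(row["Pval_Steiger"]),
            heterogeneity_flag=bool(row["heterogeneity_flag"]),
            pleiotropy_flag=bool(row["pleiotropy_flag"]),
        )


def run_sensitivity(h: HarmonizedInstruments, ivw_estimate: MREstimate,
                    egger_result: EggerResult, n_exp: int, n_out: int, *,
                    seed, alpha: float = 0.05, presso_n_sim: int = 5000) -> SensitivityReport:
    """Populate a full :class:`SensitivityReport` for one pair.

    Requires the IVW and Egger fits already computed (they parameterize the
    two Q statistics). PRESSO is skipped (``presso_global_p=None``) when
    J < 4. Flags: heterogeneity when the IVW Q p < alpha, pleiotropy when
    the Egger intercept p < alpha.
    """
    # Egger was fitted on non-negative-oriented exposure effects; the Q
    # residuals must use the same orientation.
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    h_orient = HarmonizedInstruments(
        snp_ids=list(h.snp_ids), beta_exp=h.beta_exp * sign, se_exp=h.se_exp,
        beta_out=h.beta_out * sign, se_out=h.se_out, eaf=h.eaf,
    )
    q_i, _, q_i_p = cochran_q(h, ivw_estimate.beta, df_loss=1)
    q_e, _, q_e_p = cochran_q(h_orient, egger_result.slope.beta, df_loss=2,
                              intercept=egger_result.intercept)
    if h.n_snp >= 4:
        presso = presso_test(h, n_sim=presso_n_sim, seed=seed, outlier_alpha=alpha)
        presso_p, presso_out = presso.global_p, presso.outlier_ids
    else:
        presso_p, presso_out = None, []
    st = steiger_test(h, n_exp=n_exp, n_out=n_out)
    return SensitivityReport(
        q_ivw=q_i, q_ivw_p=q_i_p, q_egger=q_e, q_egger_p=q_e_p,
        egger_intercept=egger_result.intercept,
        egger_intercept_se=egger_result.intercept_se,
        egger_intercept_p=egger_result.intercept_p,
        presso_global_p=presso_p, presso_outliers=presso_out,
        steiger_direction=st.direction, steiger_p=st.pval,
        heterogeneity_flag=q_i_p < alpha,
        pleiotropy_flag=egger_result.intercept_p < alpha,
    )
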