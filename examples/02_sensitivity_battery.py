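"""Run the sensitivity battery on data with one planted pleiotropic outlier.

One instrument's outcome effect is displaced by eight standard errors:
Cochran's Q should detect heterogeneity, MR-PRESSO should name the culprit
variant, and MR-Steiger should still confirm the exposure -> outcome
direction.
"""

import numpy as np

import mrpath as mp

cfg = mp.SimConfig(seed=11, n_snp=15, direct=0.25, gamma_sd=0.3,
                   n_out=50_000, n_cases=25_000)
exposure, _, outcome, _ = mp.simulate_triplet(cfg)
selected, _ = mp.select_instruments(exposure, None)
h = mp.harmonize(selected, outcome)

# plant an outlier: displace one variant's outcome effect by 8 SE
h.beta_out[3] += 8 * h.se_out[3]
culprit = h.snp_ids[3]

est = mp.ivw(h, model="random")
report = mp.run_sensitivity(h, est, mp.egger(h), n_exp=cfg.n_exp,
                            n_out=cfg.n_out, seed=5)

print(f"IVW (random effects): OR {mp.format_or_ci(est.beta, est.se)}, p = {est.pval:.3g}")
print(f"Cochran's Q = {report.q_ivw:.2f}, p = {report.q_ivw_p:.4f} "
      f"-> heterogeneity {'flagged' if report.heterogeneity_flag else 'absent'}")
print(f"Egger intercept = {report.egger_intercept:.4f}, p = {report.egger_intercept_p:.3f} "
      f"-> pleiotropy {'flagged' if report.pleiotropy_flag else 'absent'}")
print(f"PRESSO global p = {report.presso_global_p:.4f}, outliers = {report.presso_outliers}")
print(f"planted outlier was {culprit}: "
      f"{'recovered' if culprit in report.presso_outliers else 'missed'}")
print(f"Steiger direction exposure->outcome: {report.steiger_direction} "
      f"(p = {report.steiger_p:.2g})")
print("\nA flagged Q with the planted variant named by PRESSO shows the outlier")
print("is detectable and attributable rather than silently averaged into the estimate.")
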