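"""Screen one exposure-outcome pair: instruments, harmonization, estimators.

Simulates a microbiome-style exposure with a true causal effect of 0.30
(log-OR per SD) on a binary outcome, runs the instrument QC chain
(p < 1e-5, MHC exclusion, LD clumping, F > 10), harmonizes alleles, and
prints every estimator's odds ratio. With strong instruments all five
methods should agree with each other and with the simulated truth.
"""

import mrpath as mp

cfg = mp.SimConfig(seed=3, n_snp=20, direct=0.30, gamma_sd=0.3,
                   n_out=50_000, n_cases=25_000, ld_block_size=2, ld_rho=0.8)
exposure, _, outcome, truth = mp.simulate_triplet(cfg)
ld = mp.simulate_ld(cfg)

selected, counts = mp.select_instruments(exposure, ld, mp.ClumpConfig())
print("instrument chain counts:", counts)

h = mp.harmonize(selected, outcome)
print(f"harmonized J = {h.n_snp} (flipped {h.n_flipped}, "
      f"palindromic dropped {h.n_dropped_palindromic})\n")

print(f"{'method':16s} {'n_snp':>5s}  {'OR (95% CI)':>22s}  {'p':>8s}")
for est in mp.all_estimates(h, seed=1):
    print(f"{est.method:16s} {est.n_snp:5d}  {mp.format_or_ci(est.beta, est.se):>22s}  {est.pval:8.2g}")
print(f"\ntrue effect: log-OR {cfg.beta_all:.2f} -> OR {2.718281828**cfg.beta_all:.2f}")
print("Each row is one estimator's causal odds ratio per SD of exposure;")
print("agreement across methods indicates no estimator-specific assumption is driving the result.")
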