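# Methods

## Model and scope

`mrpath` implements two-sample summary-data Mendelian randomization. The
data unit is a per-variant association record (effect allele, other
allele, EAF, beta, SE, p, n); the exposure and outcome effects come from
non-overlapping GWAS samples. Binary outcomes are analyzed on the
log-odds scale and reported as OR with 95% CI; continuous traits are in
SD units. Causal estimates assume the three IV conditions (relevance,
independence, exclusion restriction); the sensitivity battery probes the
third.

## Harmonization

Variants are matched on identifier (an optional chromosome+position
fallback exists because identifiers are more stable across builds than
positions). Outcome effects reported on the swapped allele pair — or its
reverse complement — are sign-flipped, with EAF reflected. Palindromic
variants (A/T, C/G) cannot be strand-resolved from allele letters;
following standard practice they are dropped when EAF is missing or
within 0.5 ± 0.08 in either study (window configurable), and otherwise
aligned by requiring the two EAFs to fall on the same side of 0.5.
Frequency alignment uses the EAF columns of the input tables themselves;
no external reference panel is bundled. Irreconcilable allele pairs are
dropped with a warning, not fatal.

## Instrument selection

The QC chain runs in fixed order — p-filter, region exclusion, LD clump,
F-filter — and logs the record count after each stage (each stage is
non-increasing). Defaults: selection at p < 1e-5 (5e-5 for reverse MR,
where outcome GWAS rarely have genome-wide hits); MHC
chr6:28,477,897–33,448,354 excluded (1-based, closed interval; dense LD
and immune pleiotropy make instruments there untrustworthy); greedy
clumping with a 10,000 kb window and r² < 0.001 (1,000 kb is the
convention for dense metabolite panels); F = β²/se² strictly greater
than 10. All threshold comparisons are strict inequalities. Clumping
sorts by p ascending with ties broken by genomic coordinate, making the
output deterministic; a variant missing from the LD matrix errors in
strict mode and is treated as independent (logged) in lenient mode,
since no published rule exists for that case. LD is supplied by the user
or the simulator as an r² matrix; computing LD from genotype panels is
out of scope.

## Estimators

Per-variant Wald ratios use the first-order variance se_out²/beta_exp²
(exposure-side noise ignored — adequate when F is large); a second-order
option adds θ²·se_exp²/beta_exp². IVW is the primary estimator; the
random-effects variant (default in screening) uses the multiplicative
overdispersion model, inflating the fixed-effects SE by √(Q/(J−1))
floored at 1 so heterogeneity can widen but never narrow the interval.
MR-Egger reorients exposure effects non-negative by default (recorded in
output; an off switch exists), fits WLS with weights 1/se_out², scales
coefficient SEs by max(1, residual SD), and uses t references with J−2
df. The weighted median interpolates the inverse-variance-weighted
cumulative distribution of sorted ratios at 1/2. The mode estimators
take the argmax of a normal-kernel density over the ratios (uniform or
inverse-variance weights) with bandwidth φ·0.9·min(sd, iqr/1.349)·J^(−1/5)
on a 512-point grid spanning [min−3h, max+3h]; identical ratios
short-circuit to the common value. Median/mode SEs come from a seeded
parametric bootstrap (1000 draws by default) resampling both effect
vectors from normal(observed, SE); the mode uses the normal-scaled MAD
of the bootstrap distribution rather than its SD, because the bootstrap
distribution of a KDE argmax occasionally jumps between density peaks
and the SD then badly over-states the spread (coverage above 98% in our
recovery checks; with the MAD, coverage sits at the nominal level).
Minimum instrument counts: 1 (Wald/fixed IVW), 2 (random-effects IVW),
3 (Egger, median, modes), 4 (PRESSO).

## Sensitivity battery

Cochran's Q is the weighted residual sum of squares around the pooled
estimate, χ²(J−1) under homogeneity; the Egger variant uses residuals
from the intercept fit with J−2 df. MR-PRESSO simulates the null of the
observed leave-one-out residual sum of squares (outcome effects redrawn
at their leave-one-out predictions, leave-one-out estimates re-fitted per
draw); Monte-Carlo p-values use add-one smoothing (1+k)/(1+n_sim) so they
are never zero, and per-variant outlier flags apply Bonferroni at
α/J (the multiplicity rule is configurable; conservative by default).
MR-Steiger compares instrument variance explained in exposure versus
outcome using the z-based pseudo-r², z²/(z²+n−2), applied uniformly to
both traits — an approximation on the binary-outcome log-odds scale,
accepted here because a uniform pseudo-r² keeps the two aggregates
commensurable — with a two-sample Fisher-z test on the aggregate
correlations. The PRESSO distortion test is out of scope.

## Screening decisions and reverse MR

A pair is flagged causal only as a conjunction: IVW p < α, no
Egger-intercept flag, Steiger direction true, reverse MR null.
Heterogeneity does not veto; it switches nothing off because the
random-effects IVW already absorbs it (the flag is still reported). No
multiple-testing correction is applied across exposures by default —
matching common screening practice at α = 0.05 per pair — but Bonferroni
and Benjamini-Hochberg switches exist and are logged when enabled.

Reverse MR re-runs the analysis with roles swapped at the laxer
threshold. One subtlety: when the forward effect is strong and the
outcome GWAS well powered, the exposure's instruments show real outcome
associations and leak into the reverse instrument set, producing a
spurious "reverse" signal. The reverse analysis therefore carries its own
Steiger test; a significant reverse association whose Steiger direction
points back toward the forward orientation is discounted rather than
used as a veto. An untestable reverse analysis (no instruments at the
reverse threshold — typical for rare outcomes) counts as null.

## Two-step mediation

Step 1 estimates β₁ (exposure→mediator) with the exposure's instruments
and gates at p < 0.05 (configurable); a failed gate returns an explicit
not-mediated result carrying the gating p. Step 2 estimates β₂
(mediator→outcome) by univariable MR with the mediator's own
instruments; mediator instruments that are also exposure instruments are
excluded, since they reach the outcome through the exposure as well and
would bias β₂ (β₂ is deliberately not multivariable-adjusted for the
exposure — a documented limitation of the univariable design). The
indirect effect is β₁β₂ exactly; its SE is the first-order delta formula
√(β₁²se₂² + β₂²se₁²) (an exact-product flag adds the se₁²se₂² cross
term) or a seeded parametric bootstrap (1000 reps, percentile or normal
CI), with β₁ and β₂ sampling errors treated as independent because they
come from distinct GWAS samples. The proportion β₁β₂/β_all is reported
signed with a `consistent_signs` flag: when the indirect and total
effects disagree in sign the mediator cannot explain the total effect,
and the package surfaces that instead of taking absolute values. A
percentile-bootstrap CI for the proportion draws the three components
independently.

## Synthetic data generator

Simulation is at summary level (no genotypes): per-variant sampling SEs
follow 1/√(2·maf·(1−maf)·n) for variance-standardized traits, with
binary-outcome SEs inflated by 1/√(φ(1−φ)) (φ the case fraction) on the
log-odds scale — this reproduces the very wide intervals a rare outcome
produces without simulating liabilities. Observed effects are truth plus
normal noise at the per-variant SE. Exposure instruments carry effects
γ_j ~ N(0, γ_sd²); the mediator receives β₁γ_j plus optional pleiotropy;
the outcome receives (direct + β₁β₂)γ_j plus pleiotropy
α_j ~ N(μ_α, σ_α²). A second, disjoint panel of mediator-specific
instruments (δ_j on the mediator, β₂δ_j on the outcome, zero exposure
effect) exists because Step 2 needs instruments for the mediator that
are independent of the exposure — without them the ratio at exposure
variants identifies (direct+β₁β₂)/β₁, not β₂. LD is block-diagonal AR(1)
(r² = ρ^{2|i−j|} within blocks), with blocks positioned well inside a
clumping window and far apart across blocks.

Defaults mirror the motivating study design: 12 instruments, exposure
n = 7,738, mediator n = 8,299, outcome n = 345,187 with 69 cases. What
the generator does not emulate: realistic allele-frequency spectra,
population structure, sample overlap between GWAS, winner's-curse beyond
the explicit p-threshold selection, and LD beyond block-AR(1) — so
passing tests demonstrate correctness of the estimators and pipeline
under their stated assumptions, not robustness to those real-data
complications.

## Verification scenarios and numerical choices

Type-I calibration of Q, the Egger intercept, and PRESSO uses 2,000 null
replicates at J = 100 strong instruments (γ_sd = 0.3, exposure
n = 7,738, balanced binary outcome n = 20,000). J is large here because
the spec'd max(1, σ̂) floor on Egger SEs is deliberately conservative
and most so at small J (measured type-I ≈ 0.025 at J = 20 versus ≈ 0.048
at J = 100); large J is the regime where the test's nominal level is
meaningful. Parameter recovery uses 1,000 replicates of the full
generator→selection→harmonization→mediation pipeline at J = 50,
β₁ = 0.3, β₂ = 0.5, direct = 0.15, balanced outcome n = 20,000 — chosen
so all three component estimates are in the large-z regime where the
delta-method and percentile-bootstrap intervals are trustworthy; the
rare-outcome default deliberately is not that regime. PRESSO calibration
and outlier recovery use n_sim = 1,000 (default 5,000 in the API).
Monte-Carlo p floors at 1/(n_sim+1). Degenerate inputs: zero exposure
effect raises an undefined-ratio error; identical ratios return the
common value with Q = 0; zero total effect makes the mediation
proportion an explicit error, never ±inf.

## Known limitations

First-order ratio variances bias coverage slightly when the outcome GWAS
is much more precise than the instrument effects (the random-effects
inflation absorbs most of it). The pseudo-r² Steiger approximation on
the log-odds scale has no formal calibration guarantee for rare
outcomes. β₂ and the decomposition are univariable; with a strong
exposure→mediator path and direct pleiotropic instruments the
decomposition identity indirect + direct = total holds only in
expectation under the generator's assumptions. Published mediation
proportions from screening studies are generally computed from
unrounded internal estimates and cannot be reproduced exactly from
printed rounded ORs; this package therefore validates the reporting
arithmetic via the Wald round-trip of printed (OR, CI, p) triples
instead.
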