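# mrpath

Two-sample Mendelian randomization (MR) with two-step mediation, built for
screening designs of the kind used in gut-microbiome epidemiology: many
exposures with only genome-wide-suggestive instruments, a rare binary
outcome, candidate mediators (metabolites, immune phenotypes), and a full
sensitivity battery behind every estimate.

MR uses genetic variants as instrumental variables. For instrument *j* with
effect $\hat\gamma_j$ (SE $\sigma_{X_j}$) on the exposure and
$\hat\Gamma_j$ (SE $\sigma_{Y_j}$) on the outcome, each variant gives a
Wald ratio $\hat\theta_j = \hat\Gamma_j/\hat\gamma_j$. The package
implements the standard pooling estimators and diagnostics:

- **IVW** (primary): $\hat\theta = \sum w_j \hat\theta_j / \sum w_j$ with
  $w_j = \hat\gamma_j^2/\sigma_{Y_j}^2$; random-effects SE inflated by
  $\max(1, \sqrt{Q/(J-1)})$.
- **MR-Egger**: WLS of $\hat\Gamma_j$ on $\hat\gamma_j$ with a free
  intercept $\alpha$ quantifying directional pleiotropy (InSIDE).
- **Weighted median** and **simple/weighted mode** estimators, robust to
  subsets of invalid instruments.
- **Sensitivity**: Cochran's $Q$, Egger intercept test, MR-PRESSO global
  and outlier tests, MR-Steiger directionality.
- **Two-step mediation**: $\beta_1$ (exposure→mediator) and $\beta_2$
  (mediator→outcome) by univariable IVW; indirect effect
  $\beta_1\beta_2$ with delta-method
  ($\mathrm{se} = \sqrt{\beta_1^2\mathrm{se}_2^2 + \beta_2^2\mathrm{se}_1^2}$)
  or bootstrap CIs; mediation proportion $\beta_1\beta_2/\beta_{\rm all}$.
- **Instrument QC**: p-value threshold (default $p<10^{-5}$), MHC
  exclusion (chr6:28,477,897–33,448,354), greedy LD clumping (10,000 kb,
  $r^2<0.001$), weak-instrument filter $F=\beta^2/\mathrm{se}^2 > 10$.
- **Synthetic data**: a summary-level GWAS generator with known causal
  structure, pleiotropy, and block-wise LD, so every pipeline stage is
  testable at desk scale.

## Worked example

`examples/03_two_step_mediation.py` simulates an exposure→mediator→outcome
triplet with true $\beta_1=0.3$, $\beta_2=0.5$, direct effect 0.15 (total
0.30, so the mediator carries 50%), selects instruments, and runs the
two-step decomposition:

```
step-1 gate: p = 2.9e-304 -> proceed
beta1 (exposure->mediator) = 0.301 (SE 0.008)   [truth 0.30]
beta2 (mediator->outcome)  = 0.482 (SE 0.015)   [truth 0.50]
indirect = beta1*beta2     = 0.145 (95% CI 0.133 to 0.157)   [truth 0.15]
total effect               = 0.298 (SE 0.012)   [truth 0.30]
mediation proportion       = 48.7%   [truth 50%]
signs consistent: True
```

Each line is an IVW estimate on the log-odds scale; the proportion is the
share of the exposure's total effect flowing through the mediator, and a
mediator opposing the total effect would be reported with
`consistent_signs: False` rather than hidden. The other examples cover
single-pair screening with all five estimators (`01`), the sensitivity
battery recovering a planted pleiotropic outlier (`02`), and a batch
forward screen with reverse MR and report files (`04`). A thin CLI mirrors
the batch workflow: `mrpath simulate | screen | reverse | mediate | report`.

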