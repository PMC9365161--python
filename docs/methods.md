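# Methods

## The structural model

All estimators, diagnostics and simulations in this package refer to one
generating model for individual-level data. For participant *i*, with a
genetic instrument *G* (a single variant dosage, a polygenic score, or a
composite of *M* sub-instruments G₁..G_M), candidate interaction covariates
Z₁..Z_K, and an unmeasured confounder *U*:

```
Z_k = π_k0 + π_k1 G + ε_Zk
U   = θ0 + θ1 G + Σ_k (θ2k Z_k + θ3k G·Z_k) + ε_U
X   = γ0 + Σ_m γ1m G_m + Σ_k γ2k Z_k + Σ_mk γ3mk G_m·Z_k + γ4 U + ε_X
Y   = β0 + β1 X + Σ_m β2m G_m + Σ_k β3k Z_k + Σ_mk β4mk G_m·Z_k + β5 U + ε_Y
```

All exogenous sources and errors are independent mean-zero normals with
unit scale by default. β1 is the causal effect of interest; β2 is
horizontal pleiotropy; γ3 gives the interaction leverage (GxE1); θ3 ≠ 0
breaks interaction exogeneity (GxE2); β4 ≠ 0 breaks constant pleiotropy
(GxE3). With M > 1 the composite score Σ_m G_m plays the role of G in the
covariate and confounder layers.

## Estimators

**MR-GxE** is TSLS with G·Z_k the single excluded instrument and
{1, G, Z_k} included exogenous. Because the system is just identified, the
TSLS coefficient equals the indirect-least-squares ratio α̂3/γ̂3 of the
interaction coefficients from the outcome reduced form and the first
stage; `mr_gxe_estimand` evaluates that ratio from sample covariances and
agrees with the fit to 1e-8 relative tolerance (a property the test suite
asserts, and which the scenario runners exploit as a fast path when
fitting a hundred covariates per replicate). Standard errors are classical
TSLS asymptotics by default with a sandwich option (`robust=True`);
intervals are z-based at the fixed 95% level (multiplier 1.959964).

**MR-GENIUS** regresses X on G, forms the instrument (G − Ḡ)·ε̂ₓ from the
residuals, and runs TSLS of Y on X with that instrument and an intercept
only (the estimator targets the *total* effect; passing `adjust=`
conditions on named covariates and targets the direct effect instead).
Standard errors are heteroskedasticity-robust by default — the instrument
is itself residual-based, so classical errors understate variance — with a
seeded nonparametric bootstrap available (`n_boot`). The Breusch–Pagan
statistic of ε̂ₓ against G is reported as the identification diagnostic in
its n·R² LM form (one slope degree of freedom, chi-square reference; the
`studentized_bp=False` flag selects the original normality-based variant).

**Population oracles.** `gxe3_bias` evaluates the asymptotic MR-GxE bias
under a constant-pleiotropy violation, β4·var(GZ_k) divided by the
partialled exposure–interaction covariance (equivalently β4/γ3 in the
independent-source case), from analytic moments of the model.
`oracle_estimand_gxe2` returns the population value the estimator
converges to when the confounder covariance terms cov(U, G·Z_k) are
carried through the estimand — equal to β1 exactly when θ3k = 0, and equal
to the biased limit that simulation reproduces when θ3k ≠ 0. Both oracles
require π_k1 = 0 and a single instrument (the setting of every simulation
design); they are simulation-time tools and never see data.

## Diagnostics

* **Interaction scan (GxE1).** For every candidate covariate the first
  stage is fitted and the squared t-statistic of the interaction term is
  referenced against F(1, n−4), with a Bonferroni threshold α/K over the
  valid covariates. The variance is heteroskedasticity-robust (HC0) by
  default for a reason worth stating: when *other* covariates carry strong
  interactions, the residual of any single-covariate first stage contains
  their G·Z terms, so its variance grows with G², and the classical
  statistic for a *null* covariate becomes severely anti-conservative (at
  the default study conditions, roughly one spurious Bonferroni pass per
  replicate of a 100-covariate scan; the robust form restores the nominal
  rate). `robust=False` recovers the classical partial F, which is what
  `fit_mr_gxe` reports for its single chosen covariate, where the
  distinction is immaterial to estimation.
* **Instrument–covariate correlation (GxE2).** Pearson correlation of G
  and Z_k with its two-sided p-value. Independence is necessary but not
  sufficient for exogeneity — a three-way interaction with U can hide
  behind a zero correlation — so the result is a screen, never a proof.
* **Sub-instrument over-identification (GxE3).** When G is composite, its
  components are assorted into M groups of approximately equal strength
  (randomised greedy bin-packing on the per-column first-stage F:
  descending F, each assigned to the weakest group among those currently
  smallest, so sizes never differ by more than one; reproducible under a
  seed). The Sargan model fits one TSLS with excluded instruments
  {S_g·Z}, included exogenous {S_g} and Z (pooled Z main effect), and X
  endogenous; the statistic is n·R² of the TSLS residuals on all
  instruments and exogenous regressors, chi-square with M−1 degrees of
  freedom. Cochran's Q over the per-group estimates is provided as the
  heterogeneity-flavoured alternative; the two test the same structure and
  agree in decision on the vast majority of datasets. Identical violation
  of GxE3 across all groups is undetectable by construction — the
  violation direction then lies inside the instrument span.

## Simulation designs and default parameters

Six scenario runners cover: (1) interaction selection among K = 100
candidates of which 10 carry interactions drawn from Normal(2, 2)
truncated above 1; (2) a single-interaction sweep over target first-stage
F ∈ {1, 5, 10, 25, 50, 100}, solving γ3 from F ≈ 1 + n·γ3²·var(GZ)/σ²
with σ² = γ4² + 1; (3) the fraction of non-zero interactions from 1% to
100%; (4) GxE2 violation, θ3k = 1 on a fraction of covariates; (5) GxE3
violation, γ3k = 1 everywhere and β4k = 1 on a fraction; (6) a composite
score of M equal-strength sub-instruments (γ1m = 0.1, γ3m = 0.2,
pleiotropy β2m = 0.05, violating sub-instruments β4m = 0.2) with the
Sargan test over 9 groups. Interaction coefficients are always generated
positive so that latent interactions cannot cancel in the mean, which
would destroy MR-GENIUS identification.

Coefficients the designs do not pin down are fixed once, package-wide:
γ1 = 1 (strong instrument), γ4 = β5 = 1 (additive confounding), π_k1 = 0
(covariates independent of the instrument), θ1 = θ2 = 0, β3 = 0, and
**γ2k = 1**. The last choice is load-bearing and deliberate: with a
symmetric continuous instrument and mean-zero covariates, a pure
interaction makes var(X|G) an *even* function of G, so
cov(G, var(X|G)) = E[G³]·Σγ3² = 0 and MR-GENIUS is unidentified — the
estimator wanders and the Breusch–Pagan statistic is null. A non-zero
covariate main effect on the exposure creates the 2γ2γ3·G·Z² cross term
that makes the conditional variance linear in G and identifies the model.
Absent it, every MR-GENIUS column of the proportion designs would be
noise.

Scale: the desk profile is n = 20,000 with 200 replicates per design cell
(M = 100 sub-instruments in scenario 6); `--full` selects n = 100,000,
1,000 replicates, M = 1,000. Summaries report replicate means with the
Monte-Carlo 95% interval of the mean (1.959964 × sd/√reps); an
average-of-per-replicate-intervals view is available from the replicate
frames. One root seed spawns independent child streams per cell and
replicate, so identical configurations are bitwise reproducible.

The acceptance script reports each quantity at the desk scale; the two
mean-Sargan-p quantities use 500 replicates because a p-value mean has
per-replicate standard deviation ≈ 0.29 and warrants the tighter
Monte-Carlo error. Under both the no-violation and the identical-violation
designs the Sargan statistic's replicate mean sits at its degrees of
freedom and the mean p at one half, i.e. the test is calibrated and the
identical violation is invisible to it, as the theory predicts.

## What the simulations do and do not establish

The generator draws everything normal, linear and homoskedastic-in-errors:
real cohort data have skewed covariates, discrete dosages, non-linear and
scale-dependent interactions, and selection effects, none of which these
designs emulate. Passing tests therefore certify the estimators'
behaviour *under the stated structural model* — unbiasedness with valid
interactions, the predicted bias directions under GxE2/GxE3 violations,
calibration of the scan, Sargan and coverage — not performance on any
particular cohort. Interaction discovery and estimation on the same sample
is exposed to winner's curse; the pipeline's discovery split is plumbing
to avoid that, not a statistical correction.

## Numerical and design choices

* TSLS is solved by least squares on the projected design (QR-based
  `lstsq`), with rank checks that name the offending columns; the Sargan
  statistic uses the residual regression on the full instrument set.
* Ratio denominators (estimand, moment formulas) are guarded at 1e-12;
  degenerate interactions (var(G·Z) = 0, collinear {1, G, Z, GZ}) raise
  identification errors naming the covariate rather than silently
  dropping it.
* Missing data are removed listwise per fit, with counts logged and
  reported in `n_used`.
* Scan p-values are computed from log survival functions, so the
  −log10(p) column stays finite when p underflows.
* The per-covariate scan and the mean-over-covariates scenario columns
  share a 4×4 normal-equations fast path whose agreement with the full
  TSLS route (to 1e-15 relative) the suite asserts; designs with condition
  number above 1e12 fall back to an invalid-covariate flag.
* Result tables round-trip floats at 17 significant digits (`%.17g`);
  read them back with a round-trip float parser to recover bit-identical
  values.

## Limitations

Binary or survival outcomes, summary-statistic (stratified) MR-GxE,
fractional-polynomial interaction models, genotype-file parsing and
LD-aware score construction are out of scope; users supply numeric dosage
or score columns. The GxE2 correlation screen cannot confirm exogeneity,
only flag its violation; and no correction for a violated
constant-pleiotropy assumption is offered — the over-identification tests
detect it (except when it is identical across sub-instruments), they do
not repair it.
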