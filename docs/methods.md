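# Methods

## Data model and preprocessing

The unit of analysis is the mother-child dyad with three substantive
variables: a dichotomous breastfeeding indicator `BF`, maternal IQ `IQ_M`
and child IQ `IQ_C`, each possibly missing. Preprocessing implements the
measurement rules of the study design:

* **Breastfeeding dichotomization.** Across up to nine report occasions, a
  child counts as breastfed (1) if the mother answered "yes" at least once
  and never "no", not breastfed (0) if she answered "no" at least once, and
  missing if no response exists. A mother with both "yes" and "no" answers
  is classified 0: the never-answered-"no" clause dominates. The rule is
  order-invariant and padding-invariant.
* **IQ standardization** rescales a score vector affinely to sample mean
  100 and SD 15. The SD uses the population divisor (n), matching the
  maximum-likelihood moment convention used everywhere else in the package;
  an affine map leaves every correlation untouched, so the divisor choice
  cannot affect any model coefficient that is scale-free.
* **Child IQ** is the arithmetic mean of whatever subtest scores are
  available; missing only when all are missing.
* **Load filter.** Records missing all three substantive variables carry no
  likelihood information and are removed at load; `DyadDataset` enforces
  this invariant at construction.

CSV I/O uses comma separation, a header row and empty cells as the missing
sentinel (configurable); column roles are remappable so arbitrary exports
can be read without editing files.

## FIML moment estimation

Under a joint-normal working model the observed-data log-likelihood is
`Σ_i log N(x_i^obs; μ_O(i), Σ_O(i))`, summing each record's observed
sub-vector. Its maximizer — the FIML estimate of the mean vector μ and
covariance Σ of (BF, IQ_M, IQ_C) — is found by the classical EM algorithm
for multivariate normal data with missing values: records are grouped by
missingness pattern; the E-step fills in conditional means and accumulates
conditional covariances, the M-step recomputes (μ, Σ) with divisor n.

* **Convergence:** maximum absolute change across the nine parameters
  < 1e-8 (default), capped at 5000 iterations; non-convergence raises
  rather than returning silently. The log-likelihood trace is recorded and
  checked for monotonicity on every run — a decrease beyond round-off is a
  bug by EM's ascent guarantee. The saturated model converges in one
  effective step on complete data and in tens of iterations under realistic
  missingness.
* **Initialization:** pairwise-available-case moments, ridge-repaired to
  positive definite. This starts essentially at the solution when
  missingness is light.
* **Binary BF in a normal likelihood.** BF enters the joint likelihood as a
  plain numeric variable — the standard structural-equation treatment of an
  exogenous binary covariate under FIML, and the treatment that reproduces
  conventional SEM estimates. Consequences for standard errors are noted
  below.
* **Observed information** is the negative Hessian of the observed-data
  log-likelihood by central finite differences (relative step 1e-5 per
  parameter, symmetrized). An indefinite result raises, flagging a
  non-maximum. Expected information would differ slightly in finite
  samples; observed information is the default because it is what the data
  at hand support.

## The three saturated LCS parameterizations

With loadings fixed to one, the child intercept and residual variance fixed
to zero, and the change score Δ = IQ_C − IQ_M (or its negative for the
backward model), each parameterization is a regression of Δ read off the
moments:

* forward adjusted: Δ on (IQ_M, BF), BF and IQ_M covarying;
* backward adjusted: Δ' = IQ_M − IQ_C on (IQ_C, BF);
* forward unadjusted: Δ on BF alone, Cov(IQ_M, Δ) free.

Because each model is saturated (nine free parameters, nine moments), the
moment map *is* exact maximum likelihood, and `implied_moments` reconstructs
the input moments identically — asserted as a property test. Implementing
the models as moment maps rather than through a general SEM optimizer makes
the decomposition identities testable to machine precision and confines all
missing-data work to the FIML engine.

Standard errors propagate the inverse observed information through the
coefficient map's finite-difference Jacobian (delta method); intervals are
Wald, estimate ± 1.96·SE. A case-resampling bootstrap is available as an
alternative; on complete synthetic cohorts at n = 1500 the two agree within
about 3% for every reported coefficient, which the test suite checks at a
5% tolerance. Because BF is binary, its fourth moments differ from normal
ones, so exact agreement is not expected; empirically the effect on the
reported SEs is small.

## The decomposition

For an adjusted fit, `decompose_fit` computes the BF-group mean difference
in the conditioning IQ as d = Cov(IQ_cond, BF)/Var(BF) (exactly the group
contrast, since BF is binary) and assembles

    total = direct + d · β_IQ .

On shared moments the forward total equals the unadjusted BF effect and the
backward total equals its negative, both to exact arithmetic; the small gap
between the published -5.11 (assembled from rounded printed inputs) and
-5.13 (directly estimated) is rounding, which the tests demonstrate by
verifying the identity pre-rounding at 1e-9.

## The simulation and its oracle

The generator emulates an intergenerational null model in which any fitted
breastfeeding "effect" must be artefactual:

1. two maternal groups with true IQ N(103.3, 15.1²) (n = 1801, the
   breastfeeding group) and N(91.5, 12.4²) (n = 2763);
2. child true IQ: z_C = ρ_h·z_M + √(1−ρ_h²)·ε with ρ_h = 0.8, z-scores
   taken against the pooled maternal true distribution (ρ_h is interpreted
   as a pooled, not within-group, correlation, consistent with the pooled
   rescaling of the observed scores);
3. observed IQ: z_obs = ρ_r·z_true + √(1−ρ_r²)·η with ρ_r = 0.8, then an
   affine map to observed scales 100/15 (mothers) and 102.8/11.3
   (children).

These group sizes, moments, correlations and observed scales are the study
conditions and are the generator defaults. Breastfeeding never enters the
child equations except through the mother's group membership — the
structural guarantee that no causal effect exists to find.

The child true-score location/scale before the observed rescale is
immaterial (the rescale is affine); it is exposed as a config field so that
invariance is testable rather than assumed.

`population_moments` gives the exact population mean and covariance of
(BF, IQ_M^obs, IQ_C^obs): with p the BF proportion and σ the pooled true SD,
Cov(BF, z_M) = p(1−p)(μ_1−μ_0)/σ, and each generative step scales the
BF covariances by its ρ while the affine maps set units. The expected
coefficients of all three models follow by the same moment maps the fitted
models use. For the default configuration the expected BF effects are
+2.32 (forward adjusted), +6.07 (backward adjusted), −3.83 (forward
unadjusted): the (+, +, −) signature with zero causal effect, robust at
ρ_h = 0.7 and 0.9.

**Moment matching.** In `moment_matched` mode (the default) every noise
vector is orthogonalized against all previously constructed variables
(constant, BF, z_M, ε, η_M) and standardized, so the sample moments — group
true means/SDs, both 0.8 correlations, the observed scales, and therefore
the entire sample covariance of (BF, IQ_M, IQ_C) — equal the population
values exactly. Fitting a moment-matched cohort must then reproduce the
analytic oracle to numerical tolerance, which is the package's
parameter-recovery test. Stochastic mode (moments correct in expectation
only) is retained for consistency and sampling-theory tests. A single
integer seed drives all draws in a fixed stream order (group 1 true scores,
group 0 true scores, ε, η_M, η_C), so cohorts are bit-reproducible.

**MCAR masking** (`emulate_empirical_missingness`) reduces a complete
cohort to target per-variable observed counts by uniform masking, with a
count-preserving repair step that prevents all-missing records. It emulates
the bookkeeping of the empirical missingness (e.g. 5939/3950/4564 observed
of 6172), not its mechanism: the empirical missingness need not be MCAR,
and FIML assumes missing at random, so passing tests on MCAR fixtures shows
estimator correctness, not robustness to informative missingness.

What the generator does **not** emulate: breastfeeding duration, paternal
IQ, non-normal IQ distributions, floor/ceiling truncation of the maternal
test scale, and within-family correlation between first and second
children. Passing simulation tests therefore demonstrates the
regression-to-the-mean mechanism and estimator correctness, not that the
empirical data satisfy these idealizations.

## Pipeline choices

* Descriptive tables use pairwise-available cases (per-variable Ns) with
  divisor n−1, the descriptive convention; model fitting never uses them —
  it uses FIML moments.
* Split-half cross-validation draws a uniform random partition into halves
  of size ⌈n/2⌉ and ⌊n/2⌋ (unstratified; the split seed is a documented
  flag, default 20220516). Subsample estimates are reported against the
  full-sample estimate, not enforced to agree.
* p-values are two-sided Wald and carried in reports only; no
  multiple-testing machinery is attached, since the design question is sign
  divergence between models, not significance hunting.
* Configs serialize as JSON.

## Problem sizes used by the test suite

Unit and property tests run on cohorts of 120-1800 dyads, the Monte-Carlo
check of the analytic moments on one million dyads, the FIML consistency
check on 200 masked cohorts at the default n = 4564, and the brute-force
likelihood oracle on a six-record toy with two missing cells — chosen so the
whole suite completes in about a minute while each check retains the
resolution its tolerance needs (e.g. four Monte-Carlo standard errors, or
1e-6 against the analytic oracle).

## Known limitations

* The empirical extract cannot be redistributed; the empirical acceptance
  check requires downloading it, and the split-half driver otherwise runs
  on a synthetic stand-in matched to the descriptive moments (labelled as
  such), whose fitted effects differ mildly from the published ones because
  descriptive pairwise moments are not the FIML moments of the raw data.
* Delta-method SEs use the normal-theory observed information although BF
  is Bernoulli; the bootstrap flag exists for users who want
  distribution-free uncertainty.
* The FIML engine is specialized to three variables; it is not a general
  p-variate SEM, and MNAR sensitivity analysis is out of scope.
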