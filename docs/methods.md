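# Methods

## The measurement model

`gtrel` treats a trial-level psychophysiological score (a single-trial
ERN amplitude, a per-split RMSSD, a rectified EMG magnitude) as the sum
of a grand mean, a person effect, facet effects, their interactions,
and residual error.  For the one-facet Persons × Trials design,

    X_pi = μ + (μ_p − μ) + (μ_i − μ) + (X_pi − μ_p − μ_i + μ),

with variance decomposition σ²_X = σ²_p + σ²_i + σ²_pi,e.  Because
there is one observation per (person, trial) cell, the highest-order
interaction is confounded with residual measurement error — its label
always carries the `,e` suffix.  Two-facet (× Occasions) and split
(Persons × (Trials:Splits)) designs extend the decomposition in the
obvious way; the full effect sets per layout are in
`gtrel.core.LAYOUT_EFFECTS`.

The person is the object of measurement: reliability coefficients are
ratios of universe-score (person) variance to universe-score variance
plus error.  *Relative* error variance collects only person × facet
interaction terms (error that reorders people); *absolute* error adds
facet mean-level terms (error that moves everyone).  The
generalizability coefficient Eρ² uses relative error, the dependability
coefficient φ uses absolute error, and the two coincide exactly when
all facet main-effect variances are zero — an identity the test suite
asserts.

Coefficients of equivalence (CE), stability (CS), and combined
equivalence-and-stability (CES) reallocate the person × occasion or
person × trial interaction into the universe score for the two-facet
design, giving internal-consistency and test-retest analogs.
Cut-score dependability adds (μ − C)² to the signal: decisions about a
threshold far from the mean replicate more easily.  When C = μ it
reduces exactly to global dependability (asserted).

## Estimators

**Expected mean squares (`estimate_ems`).**  For balanced Gaussian
designs the random-effects ANOVA expected-mean-square equations are
solved exactly; this is the oracle the Bayesian path is tested
against.  Raw solutions can be negative (e.g., when a facet contributes
no variance); they are reported in `raw_components`, truncated to zero
for downstream coefficients, and flagged per component.  Unbalanced
tables are refused with a pointer to the Bayesian path.

**Bayesian multilevel (`estimate_bayes`).**  The same decomposition is
fit as a multilevel model by a conditionally-conjugate Gibbs sampler
(`gtrel._gibbs`).  Priors on component SDs are half-Student-t with 3
degrees of freedom, scaled by the observed score SD — weakly
informative in the units of the modality — implemented through the
Huang–Wand inverse-gamma auxiliary representation so that every full
conditional stays inverse gamma and every variance draw is strictly
positive.  Unbalance is handled naturally by the likelihood.  Point
estimates are posterior medians; uncertainty is reported as 95%
equal-tailed credible intervals.

Two reparameterization moves keep the chains mixing in crossed
designs, where the flat cell mean, the effect means, and interaction
margins are only weakly identified jointly: after each block update the
sampler (a) shifts the block's mean into the cell mean and (b) shifts
an interaction's per-parent-level means into the parent main effect,
each shift drawn from its exact full conditional along the
likelihood-invariant direction.  Both moves are exact Gibbs steps on an
equivalent parameterization; they change mixing, not the posterior.

**Convergence rule.**  Split R-hat is computed (via arviz) for every
variance parameter and cell mean; estimation fails loudly when any
exceeds 1.01.  A Gibbs sampler has no divergence diagnostic, so the
R-hat gate is the entire rule.  Default chain settings are 4 chains ×
1000 draws after 500 warmup iterations; layouts with interaction blocks
default to thinning of 5 (and 800 warmup) because interaction variances
decorrelate more slowly than main effects.  The worked three-task
example in the tests and the acceptance script uses thin = 12: trial
effects observed on ~12–21% of persons per trial are the slowest-mixing
parameters in the package.

**Fixed facets and heteroscedasticity.**  Fixed facets (task, event
type) enter the mean structure as per-cell means, and every random
effect block is nested within fixed cells with its own variance per
cell — a single joint location-scale model that yields per-condition
person/trial/residual components (`components_by_fixed_level`) and
hence per-condition reliability with full posterior uncertainty and
post-estimation contrasts.  With `heteroscedastic_by` the residual
variances are grouped by that facet's conditions and share one
higher-level auxiliary scale (a "distribution of variances"), so
variance heterogeneity is estimated, not assumed away.  For EMS with a
fixed facet, components are estimated per cell and the top-level map is
the unweighted across-cell mean; per-cell sets are retained.

**Non-Gaussian families.**  `lognormal` models the decomposition on
log scores (strictly positive, right-skewed measures such as spectral
power); `gamma_chisq` models it on square-root scores, a
variance-stabilizing choice for power-like, zero-bounded measures with
a noise floor.  All components and coefficients are then reported on
the modeling scale, and every report names that scale.  The choice to
define reliability on the transformed scale (rather than
back-transforming) keeps the linear decomposition exact and is stated
in every output; it is a genuine design choice, since reliability of a
transformed score has no single canonical scale.

**Covariance components (difference scores).**  For a two-measure
table the person-level covariance σ_XY(p) is always estimable; error
covariances exist only when X and Y are concurrent (observed on the
same trials) and are exactly zero otherwise — non-co-occurring events
cannot share error.  The EMS path uses bivariate mean cross-products
(the direct analog of the univariate EMS equations) for one- and
two-facet designs.  The Bayesian path (one-facet) gives the paired
person effects (and, when concurrent, trial effects and residuals) a
bivariate normal distribution with inverse-Wishart priors (df 3, scale
diag of the observed per-measure variances), so every covariance draw
respects the Cauchy–Schwarz bound by construction.  EMS covariance
estimates are clipped to the bound with an explicit flag, never
silently.

## D study

Error variances and coefficients follow the closed forms of the
one-facet, two-facet, and split designs, evaluated at user-chosen
replicate counts n′.  When the G study produced draws, each coefficient
is computed per draw and summarized by median and 95% CrI — the
coefficient of the median components is not the median coefficient, so
per-draw evaluation is the only faithful propagation.  SEMs are square
roots of the corresponding error variances (a SEM is a standard
deviation by definition).  Projection grids report the smallest n′
reaching a target (ties toward the smaller n′) and, when the target is
unreachable, the asymptote obtained by sending the varied count to
infinity — terms without that count in their denominator survive and
cap the coefficient.

The Persons × (Trials:Splits) × Occasions layout is supported in the
coefficient engine only, as an explicit composition of the occasion
design's terms with the split design's terms over the full crossed
effect set; it is labeled experimental because no closed published form
was available to check it against, and no estimator is offered for it.

### Difference scores

The universe-score variance of a difference D = X − Y is
σ²_X(p) + σ²_Y(p) − 2σ_XY(p); error terms enter at each measure's own
replicate count, and covariance terms are divided by the harmonic mean
n̈ = 2/(1/n_X + 1/n_Y) of the two counts.  For the two-facet design the
CE variant adds the person × occasion terms to the numerator and the CS
variant the person × trial terms.  A numerator at or below zero is a
first-class *undefined* result carrying a diagnostic message — absent
between-person variance in change means the difference score cannot be
evaluated for individual differences, which is information about the
measure, not an estimation failure.  Only relative (G-type) variants
are defined for differences; an absolute variant would need facet-mean
covariance terms whose form is not established, so none is offered.

`ceiling_analysis` sweeps the person-level correlation from 0 to 1
(variances and error terms fixed) to show how constituent overlap caps
difference reliability — at r = 1 with equal variances the difference
signal vanishes entirely.

## Synthetic data

The generator draws each effect from a normal distribution with its
stated variance and sums them, so the estimators' assumptions hold
exactly by construction; non-Gaussian families exponentiate or square
the latent decomposition (the components are then defined on the
latent scale — the same scale the estimators use).  Per-person
unbalance keeps each trial independently with a stated retention
probability, independent of scores: missingness is ignorable by
construction, matching the estimators' assumption.  Two trials per
person are always retained (the person's first two, chosen without
looking at scores) so no cell degenerates.  Zero-inflation (EDA
nonresponse) zeroes a stated fraction of scores after the family
transform.  One global seed drives everything, with fixed per-purpose
spawn keys so adding a facet never reshuffles another facet's draws;
equal specs and seeds give byte-identical CSVs.

What the generator does *not* emulate: informative missingness
(artifact rejection correlated with amplitude), serial dependence
across trials (habituation, drift), latency jitter, and non-exchangeable
trials.  Passing tests therefore show that the estimators recover the
model they assume — they do not certify behavior under violations of
exchangeability or ignorability.

### The worked three-task example

`make_worked_example` emulates an error-monitoring study: three tasks
(flanker, Stroop, go/no-go) of 420 trials each, in which only
commission-error trials yield a score.  All tasks share the same
generating components (σ²_p = 1, σ²_i = 0.5, σ²_pi,e = 10, μ = −8 µV
— per-trial ICC ≈ 0.09, in the range typical of single-trial ERP
scores), but error rates differ (21%, 17%, 12%), so usable-trial counts
differ (~88, ~71, ~50 per person).  The structural consequence, which
tests and the acceptance script verify: per-trial ICCs match across
tasks while dependability at the observed counts is ordered by count,
and evaluating all tasks at one common count removes the differences.
Magnitudes of psychophysiological variance components have no canonical
values; these defaults were chosen for test power and plausibility, not
as a claim about any real dataset.

## Numerical choices and edge cases

- All-zero components make every coefficient 0/0; this raises
  `UndefinedCoefficientError` rather than returning 0.
- σ²_p = 0 with positive error gives coefficient 0 (a valid value).
- Replicate counts accept `math.inf` for asymptote evaluation.
- The cut-score term uses the estimated grand mean with no small-sample
  bias correction.
- Posterior medians (not means) summarize skewed variance posteriors.
- The MCMC seed is a mandatory argument; there is no default stream.
- With very few conditions (e.g., two occasions) the posterior of that
  facet's variance is wide and prior-influenced; the credible interval,
  not the point estimate, is the honest summary there.

## Problem sizes used in the test suite

Oracle-equivalence and recovery checks run at 150 persons × 40 trials
(Bayes vs EMS), 50 replicates of 200 × 50 (EMS bias), 150 × 60 × 2
tasks (heteroscedastic recovery), and 100 persons × 3 tasks × 420
trials with retention (worked example).  These sizes give sampling
error comfortably inside the asserted tolerances while keeping the
whole suite around a minute of compute.

## Known limitations

- No REML/frequentist mixed-model backend; external cross-checks are
  the caller's responsibility.
- Cross-classified structures beyond the four supported layouts (e.g.,
  trials nested in persons with unequal split lengths) are not modeled;
  uneven split lengths must be resolved by the caller (harmonic-mean
  counts are one defensible choice for n′ per split).
- Bayesian covariance estimation covers the one-facet design;
  two-facet covariance components use the EMS path.
- Multivariate/bifactor designs (composite scores with subscale
  weighting) are out of scope; only the covariance components needed
  for difference scores are provided.
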