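# Methods

## Model

`ginvest` fits a four-factor Bayesian structural equation model for
grandchild-reported grandparental investment.  Each grandparent type
g ∈ {MGM, MGF, PGM, PGF} has a latent investment score η_g measured by four
ordinal items (Q15, Q26, Q27 on 1–4 scales, Q38 on 1–3) through a probit
threshold link: an underlying continuous response y* = λ η + ε with ε ~ N(0,1)
is cut at item thresholds τ into the observed category.  The indicator
residual variance is fixed at 1 (theta parameterisation), which together with
the marker constraint λ_Q38 = 1 sets the latent scale.

Partial measurement invariance is imposed rather than estimated: thresholds
are shared by all four grandparent types, all loadings are shared except one
item's (Q15 by default, configurable), which is type-specific.  The marker
can never be the free item.

The structural model regresses each factor on the alive/dead flags of the
*other three* grandparent types plus grandchild age (centered at its sample
mean, for numerical stability under the diffuse N(0, 100²) coefficient
prior — slopes are unchanged, intercepts are reinterpreted).  A factor is
never regressed on its own alive flag.  The latent errors ζ are jointly
normal with an unstructured 4×4 covariance Ψ (inverse-Wishart(I₄, df 5)
prior), absorbing unmeasured within- and between-lineage influences.

Latent locations need one more constraint because shared thresholds make
latent means comparable across types: the maternal grandmother's structural
intercept is fixed at 0 and the other three intercepts are free.  This is a
documented assumption — the choice of reference does not affect the
between-type contrasts.

Missing responses — all items of a deceased grandparent, plus sporadic item
nonresponse — contribute no likelihood terms; the grandchild stays in the
model and information flows through the joint latent structure (MAR,
full-information estimation).

## Sampler

Estimation is a Gibbs sampler with truncated-normal data augmentation.  Per
sweep, in fixed order:

1. **y\*** — each observed ordinal cell from N(λη, 1) truncated to its
   category's threshold interval (inverse-CDF with tail-stable reflection);
2. **η** — each grandchild's 4-vector from its exact multivariate-normal full
   conditional (precision Ψ⁻¹ + diag Σλ² over observed cells);
3. **λ** — conjugate normal per free loading, pooling sufficient statistics
   across equality-tied cells;
4. **τ** — each interior threshold from its N(0,1) prior truncated to
   (max y* in the category below, min y* in the category above), pooled over
   tied cells, falling back to the neighbouring thresholds when a category is
   empty; ordering is preserved by construction.  This truncated-prior
   conditional mixes slowly for thresholds, which is why heavy thinning is
   the default (a joint Metropolis threshold update is out of scope);
5. **(β, α)** — one joint multivariate-normal draw of the stacked coefficient
   block, exploiting the seemingly-unrelated-regressions structure across the
   four equations (cross-products precomputed once);
6. **Ψ** — inverse-Wishart(I₄ + residual outer products, 5 + n), via Bartlett
   decomposition.

Initialisation is deterministic given the seed: free loadings at 1,
thresholds at inverse-normal cuts of the marginal category proportions,
β = α = 0, Ψ = I, η = 0, y* drawn once from the implied truncated normals.
Chains are seeded from a `SeedSequence` of (base seed, chain id), so results
are independent of scheduling and bit-reproducible.

The production path fuses all six updates into one compiled (numba) sweep;
a step-wise numpy driver implements the identical conditionals and is used
in unit tests (the suite checks both paths agree).  The normal quantile
inside kernels is Wichura's PPND16 approximation (≤3e-15 absolute error).
Items can be declared continuous, which bypasses augmentation (y* ≡ data) —
the linear-Gaussian degenerate mode used by the exactness tests; Ψ can be
held fixed for the same purpose.

Default MCMC settings mirror the emulated study: 3 chains × 300,000
iterations per chain, burn-in 150,000, thinned by 50.  The test-suite and the
acceptance script use 3 × 20,000 (burn-in 10,000, thin 10) at n = 1411, where
structural Gelman–Rubin factors are typically below 1.08; the reference
equation's coefficients, which share level information with the slowly-mixing
shared thresholds (that equation has no free intercept), occasionally reach
≈1.1 at these settings.  Smaller illustrative runs use proportionally reduced
settings.

## Reporting

Point estimates are posterior medians; intervals are 95% highest-posterior-
density intervals (shortest contiguous window containing ⌈0.95 n⌉ sorted
draws, ties broken at the lowest start).  The one-tailed p is the posterior
mass strictly on the opposite side of zero from the median (0.5 when the
median is exactly zero; exact zeros are excluded from both tails — a
measure-zero event for continuous parameters).  PSRF is the classic
√(((n−1)/n · W + B/n)/W) on the retained (thinned, post-burn-in) draws of
unsplit chains, with 1.1/1.2 reported as strict/lenient convergence flags and
a degenerate flag when W = 0.  Latent correlations are computed per draw from
Ψ and then summarised (the nonlinear transform precedes the median, not the
other way around).  Effective sample sizes come from arviz.

Marginal effects report the marker item's category probabilities with a
predictor at 0 vs 1 and other covariates at sample means.  By default they
are population-averaged: the total underlying SD is √(λ²ζ_focal + 1),
integrating the focal factor's residual; a conditional (ζ = 0) mode is a
flag.  They are evaluated at posterior medians by default; a propagation
flag instead pushes every retained draw through the probability transform
and summarises by the per-category median.

## Phantom sensitivity analysis

Unmeasured within-lineage confounding (e.g. household resources affecting
both a grandparent's survival and the spouse's investment) is mimicked by a
phantom variable: a latent with no indicators, mean fixed at 0 and variance
at 1, with two *fixed* paths of equal size γ — one into the focal factor's
structural equation, one into the spouse's survival flag.  The survival flag
becomes endogenous through a linear auxiliary equation a = ν + γφ + δ with a
free intercept and an inverse-gamma(0.001, 0.001) residual variance (a
probit auxiliary is available as a toggle; the linear form matches the
fixed-constant path logic and the 0/1 coding).  Between-lineage confounding
is deliberately not modelled.  The scan fits the base model plus 1× and 2×
variants, with γ defaulting to the largest within-lineage effect in the
current base fit, and flags coefficients whose HPD excludes zero in the base
fit but not under confounding.  A phantom with γ = 0 is an exact no-op on
the stationary distribution.

## Synthetic cohort generator

Because the original survey data are safeguarded, the generator emulates the
study conditions: survival proportions 0.837/0.688/0.732/0.571 per type,
independent Bernoulli per cell with all-dead rows redrawn so every grandchild
has a living grandparent (this inclusion rule lifts marginal survival by a
few tenths of a percent — measured, and accepted); ages truncated to [11, 16]
with the underlying normal calibrated (numerically) so the *observed*
truncated moments are 13.39/1.41; n = 1411 after exclusions; the published
structural medians as true β and the published latent correlation matrix as
the Ψ correlation.  Age enters continuous (a rounding toggle exists); an
optional within-lineage spouse-survival correlation (Gaussian copula) is off
by default because the analysis treats survival flags as exogenous data.

True loadings (0.9 for non-markers), thresholds ((−1, 0, 1) for 4-point
items, (−0.6, 0.6) for the 3-point marker), latent error variances (1) and
the age slope (−0.05/yr) are **synthetic plumbing**: the study's estimates of
these are not published in its main text.  The truth object carries a
`synthetic_measurement_defaults` flag.  Item nonresponse for living
grandparents is 5%; the reverse-coded item is emitted in raw orientation so
preprocessing's reverse-scaling is genuinely exercised.  Optional confounder
paths inject a standard-normal latent with a linear shift γ_x on a survival
probability (clipped to [0.01, 0.99]) and γ_y on a latent mean, mirroring
the phantom wiring.

What passing recovery tests on these cohorts shows: the sampler and
reporting chain are correct and calibrated *under the stated generating
process*.  What they cannot show: agreement with the original study's exact
numbers, which depend on its unpublished measurement parameters and on real
response behaviour (skewed category usage, non-ignorable missingness,
clustering by school) that the generator does not emulate.  One concrete
consequence: with the plumbing measurement strength, posterior SDs of the
−0.207 cross-lineage effects are ≈0.10 at n = 1411, wider than the study's
≈0.07–0.08, so HPD-excludes-zero sign calls at those effect sizes succeed
only about half the time per replicate.

A design note on embedded-confounder experiments: when data are generated
with a confounder on an exposure whose outcome equation is the *reference*
equation (no free intercept), the base model's omitted-variable bias leaks
into other near-constant binary regressors; with a free-intercept outcome
equation the leak is absorbed.  The packaged sensitivity demonstration
therefore embeds the confounder on the paternal pair.

## Numerical choices and edge cases

- Truncated-normal sampling clamps quantile arguments to [1e-300, 1−1e-16]
  and reflects one-sided upper intervals, so extreme cells cannot produce
  infinities; a degenerate zero-mass interval returns the near bound.
- Threshold updates raise on inverted bounds (an internal invariant
  violation, not a data condition).
- `validate_spec` reports problems (self-regression, missing marker, improper
  inverse-Wishart df, out-of-range category counts) rather than raising.
- Exclusion rules run in a fixed order (no living grandparent → co-residence
  → no responses at all or missing age); counts are order-dependent and the
  log makes the order auditable.  "No responses at all" means all 16 items.
- Missingness is an explicit mask throughout, never a sentinel category.
- Empty data (n = 0) degrades gracefully: structural draws come from the
  prior; exclusion of everything is allowed.
- Pipeline outputs are byte-deterministic given (input, config, seed):
  wall-clock time is only logged to stderr, and result files embed the config
  hash and seed.

## Known limitations

- The threshold sampler's autocorrelation makes the effective sample size per
  iteration small for τ; heavy thinning is built into the defaults.
- Numeric agreement with the original study is not expected even in
  distribution: its exact parameterisation (latent response variances,
  threshold/intercept handling in its software) is not printed, and our
  identification choices are documented assumptions.
- No model-fit indices (PPP/DIC/WAIC), no configural invariance testing, no
  MNAR/selection modelling, and no support for indicators outside the 2–7
  ordinal category range.
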