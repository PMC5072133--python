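# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices, and the known limits of what the package's tests can
show.

## Population variability and its transforms

Variability of taxon *k* in treatment *t* is the sample coefficient of
variation of its abundance across the replicate slides of that treatment,
CV = s/x̄ with the n−1 standard deviation.  CV is used because it removes
first-order variance–mean scaling: multiplying all abundances of a taxon by
a constant leaves it unchanged (this is asserted exactly in the tests).  A
CV needs at least two replicates and a positive mean; a zero-mean cell is an
error, not a silent NaN.  Absent (slide, taxon) pairs are treated as true
zeros — each slide is a census of its community, not a sample with missing
entries.

The modelling response for counted assemblages is √CV, which symmetrizes
the right-skewed CV distribution.  For closed assemblages the response is
the residual of CV after detrending (below), because closure itself induces
a CV–mean relationship that would otherwise masquerade as a treatment
signal.

## Detrending closed data

Dividing abundances by the per-slide total makes a taxon's proportion
compete against the summed noise of the rest of the community: the larger
its mean share q, the more its own fluctuations cancel from the ratio.  To
first order (delta method), for independent latent abundances with common
CV c and n taxa with the remainder in equal shares,

    CV(p) ≈ c · (1 − q) · √(n/(n − 1)),

decreasing in q, tending to c for a rare taxon in a diverse community and
to 0 for a dominating taxon.  The `relcv` module validates this
approximation against simulation on a grid of mean shares 0.01–0.5 at
latent CV 0.3 and 0.5 (relative error under 15%; typically ≲5%).  The
approximation degrades for a taxon holding most of the community at high
latent CV (measured ~15% error at share 0.7, ~33% at 0.9, latent CV 0.5):
second-order terms grow with c²/(1−q).  The limits at q→0 and q→1 hold
regardless.  Note the exact q→0 limit is c·√(n/(n−1)), not c; the
difference vanishes for the many-taxon communities the module emulates.

The pipeline removes the empirical trend, rather than the analytic one, by
nonlinear least squares of cv = a·exp(b·x) on x = log mean abundance,
pooled over all (taxon, treatment) records in a single fit.  The fit is
initialized from OLS of log(cv + 1e-9) on x; the 1e-9 guards a log of zero
during initialization only and never enters the objective.  A
three-parameter variant with an additive offset is available behind a flag
(`offset=True`); the two-parameter curve, which decays to zero, is the
default.  On repeated non-convergence the log-linear initialization is
returned, flagged `converged=False` and logged.  Records whose residual
lies more than 3 SD from the residual mean are flagged as outliers in a
single pass (not iterated) and excluded from the default model fit; a flag
keeps them.

## The mixed model and profiled REML

The fixed-effects design is saturated for the 9 treatment cells: intercept,
four binary main effects (depth/scour at time 1/time 2) and the four
estimable T1×T2 interaction products.  Within-time products (e.g. depth and
scour both at time 1) are structurally zero and excluded.  A single random
intercept per taxon absorbs inherent between-taxon variability.

Estimation profiles the restricted likelihood over the variance ratio
λ = σ²_taxon/σ² on the log scale.  Because the random effect has one
grouping factor, V(λ) = I + λZZᵀ is block diagonal, and V⁻¹x, log|V| and
the GLS normal equations have closed blockwise forms — no n×n matrix is
ever formed.  The optimizer evaluates a 25-point coarse grid on
log λ ∈ [−10, 10], refines with bounded scalar minimization (xatol 1e-9),
and explicitly compares the λ = 0 boundary (pure fixed-effects model),
which handles σ²_taxon → 0 cleanly.  σ² is profiled out analytically as
the REML quadratic form over n − p.  Standard errors come from
σ̂²(XᵀV⁻¹X)⁻¹; p-values use the two-sided normal (Wald z) approximation,
with the intercept's reported as NaN in coefficient tables (its test
against zero is not meaningful here).  Per-taxon effects are best linear
unbiased predictions λZᵀV⁻¹r; in balanced designs they sum to zero.

The fitter is verified three independent ways: against a dense-matrix
2,000-point grid search over log λ, against statsmodels' MixedLM (test-only
dependency), and against the balanced-design identities (REML fixed effects
= OLS; intercept = AA cell mean; fitted treatment means = cell means).
Rank-deficient designs raise an error naming the collinear columns.

Wald calibration is checked by simulation: 200 datasets of 40 taxa drawn
directly from the mixed model (targets from the generator plus N(0, σ_resid)
cell noise), with 95% intervals required to cover each true coefficient in
95% ± 4% of replicates.  The direct draw is deliberate: see "Limits" below.

## Permutation inference

Because the response is a derived statistic (a CV, possibly detrended), the
recommended inference is permutation.  Slides are the exchangeable unit
under the null of no disturbance effect, so each replicate shuffles the
slide → treatment map (slides keep their abundance profiles, so the
within-slide dependence between taxa is preserved), recomputes the CV table
— and, for closed data, refits the detrend curve — and refits the mixed
model.  Taxon filtering depends only on slide profiles, never on labels, so
it is computed once.  Balance of the shuffled design is asserted on every
replicate.  Fit failures in a replicate are recorded and excluded, with the
effective count reported.

The pseudo-*P* of a coefficient under `lower` is the fraction of the null
strictly below the observed value (ties count as not lower); `upper` mirrors
it and `two_sided` doubles the smaller tail, capped at one.  An
add-one-corrected variant (count+1)/(n_perm+1) is always reported; it is a
valid (if slightly conservative) p-value by construction, and the
calibration test confirms the two-sided add-one variant rejects at ≤5% + 
binomial tolerance under a global-null simulation at n_perm = 199.  The
default is n_perm = 999 with the one-sided `lower` convention in summary
tables; two-sided is recommended when direction is not prespecified.
Stars follow *, **, *** for P < 0.05, 0.01, 0.001.

## Ordination and overlap

PCA is computed on column-centered, unscaled relative abundances
(covariance PCA), via SVD; correlation PCA is not offered because the
proportions share a scale.  Components are eigenvalue-ordered with each
component's sign fixed so its largest-magnitude loading is positive;
variance explained is reported in percent.  Counted assemblages are closed
to proportions before ordination; closed assemblages are not re-normalized
after taxon filtering (a deliberate default — re-closure after filtering
changes the geometry).

Treatment polygons are monotone-chain convex hulls of each treatment's
slides in the PC1/PC2 plane, counter-clockwise, with collinear vertices
dropped; degenerate inputs (fewer than 3 distinct points, all collinear)
raise an error carrying the degenerate segment.  Overlap between two
polygons is detected by vertex containment in either direction plus
edge-pair intersection (which catches cross-shaped overlaps with no
contained vertices), and quantified as the fraction of one treatment's
original points inside the other's hull.  Polygon intersection *area* is
deliberately out of scope; the scientific claim is qualitative overlap.

Dissimilarities: Sorensen on presence/absence (presence = abundance
strictly > 0; equal to Dice dissimilarity), Bray-Curtis and Euclidean on
relative abundances, all via scipy's pdist.  Pairs of all-zero slides make
Sorensen/Bray-Curtis undefined and raise an error naming the slides.  The
Mantel statistic is the Pearson correlation of upper-triangle entries, with
a joint row/column permutation null and add-one p-value; constant distance
matrices (e.g. Sorensen when every taxon is present on every slide) are
rejected rather than returning NaN.

## The synthetic generator

The generator defines the study conditions the tests run under:

- **Design**: 108 slides assigned uniformly at random with exact balance —
  36 per time-1 condition, and within each, 12 per time-2 condition.  The
  stratified second randomization forces exactly 12 slides per cell, which
  every downstream analysis assumes.
- **Targets**: the sqrt-CV of taxon k in treatment t is
  clamp(β₀ + xₜᵀβ + a_k, 0.05), with a_k ~ N(0, σ²_taxon).  Defaults are
  anchored to the fitted diatom coefficient table (intercept 1.251, main
  effects −0.155…−0.230, interactions +0.102…+0.217, taxon variance
  0.0240 — treated as a variance, a recorded reading rather than an
  assertion).  The 0.05 floor keeps CVs physical when the random intercept
  pushes the linear predictor negative; with the default effect sizes it
  never binds.
- **Abundances**: Gamma with per-taxon log-uniform mean (2 decades for the
  counted assemblage, 10–1000 per cm²; 3 decades for the latent bacterial
  scale) and CV equal to the squared target sqrt-CV, so the generative
  model coincides exactly with the fitted model.  Gamma was chosen because
  it is nonnegative with freely controllable mean and CV; a lognormal
  alternative sits behind the `distribution` flag.  CVs below 1e-8 switch
  to a normal approximation to avoid Gamma-shape overflow.  Per-taxon mean
  ranges are unanchored by any published table; any 2–3 decade log-uniform
  span is equivalent for the statistics computed here.
- **Closed profiles**: latent abundances are divided by the slide total;
  an optional detection limit zeroes proportions below a threshold and
  re-closes, to exercise the prevalence filter.  Slides closing to zero
  total are resampled and logged (impossible at default parameters).
- **Bacterial effect sizes**: the closed-assemblage preset uses
  near-null single-disturbance effects and negative same-disturbance
  interactions of published magnitude on the latent sqrt-CV scale — an
  emulation choice, since the published bacterial coefficients live on the
  residual scale, which has no direct generative analogue.
- **Seeding**: one global seed feeds a deterministic SeedSequence stream
  split per stage, so identical seeds give byte-identical tables and
  stages can be rerun independently.
- **σ_resid = 0.13** (sqrt-CV scale) is the default cell-level noise for
  direct draws from the mixed model, chosen as the Monte-Carlo standard
  deviation of the sqrt-CV estimator from 12 Gamma draws at study-like CV
  levels (measured 0.11–0.14).

What the generator does *not* emulate: immigration/colonization dynamics
between disturbances, temporal autocorrelation, taxon–taxon interactions,
ARISA peak-calling noise, and zero inflation beyond the optional detection
limit.  Passing tests therefore show that the *statistical machinery* is
correct under the assumed data-generating process, not that the process
describes any particular real community.

## Limits worth knowing

- **CV estimation at 12 replicates is biased.**  The sample CV of 12 Gamma
  draws underestimates the true CV, and √ of it more so (Monte-Carlo bias
  −0.04 to −0.08 on the sqrt-CV scale at study-like CV levels, growing
  with the target).  Consequently, a mixed model fitted to empirical CVs
  estimates the expectation of the *estimated* sqrt-CV, not the generative
  target: intercepts recovered from 12-replicate simulations sit ~0.08
  below the generative β₀.  Treatment contrasts partially cancel the bias
  but not exactly, since it depends on the CV level.  This is why the Wald
  coverage experiment draws responses directly from the mixed model — the
  claim being calibrated is about the fitter, not about small-sample CV
  estimation — and why permutation inference, which is exact under
  exchangeability regardless of estimator bias, is the recommended test.
- **Detrending pools all records in one curve** (a single fit across
  treatments); per-treatment detrending is available behind a flag but is
  not the default, and outlier removal happens once, after the pooled fit,
  before modelling.
- **Quadrant classification ties** (a treatment exactly on a grand mean)
  go to the "above" side and are logged; with continuous responses they
  have probability zero.
- **Problem sizes** used by the shipped tests and acceptance runs — 108
  slides, 8 taxa / 150 OTUs, 200-replicate calibration experiments at
  n_perm = 199, 2,000-point oracle grids — were chosen so the full suite
  completes in a few minutes on one core while keeping Monte-Carlo error
  well inside the asserted tolerances; all scale linearly if increased.
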