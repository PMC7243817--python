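# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Data model and preparation

Input records are capture events: `band_id, species, date, hour`.
Season windows are anchored on month-days (spring 15 Apr–15 Jun, fall
15 Aug–15 Nov) so the occasion count k is constant across years — 62
and 93 days respectively — and leap years cannot shift it (neither
window spans February).  Occasions are 1-based from the window start.

Preparation rules, in order: capture times are rounded to the nearest
hour (minutes ≥ 30 round up; 23:30+ clamps to 23 so a record never
rolls into the next day); records outside both windows are dropped;
within (band, date, hour) only the first record is kept; individuals
judged to overwinter are removed entirely.  The overwintering rule had
to be made concrete: the default removes individuals of a species
captured in both the fall window of year y and the spring window of
year y+1.  It is configurable (`overwinter_rule="none"`), and removed
individuals are listed in the preprocessing report, because any such
rule is a judgement call.  Counts dropped by each rule are logged and
reconciled against the input count (`n_in = n_out + dropped`).

A bird recaptured in a later year starts a fresh capture history for
that season-year: year-specific parameters are estimated from
season-length histories, and between-year survival is not modeled.
Species-season datasets are retained only when they exceed 300
individuals in total (strictly greater), matching the sampling-adequacy
convention for this kind of analysis.

## Phenology: quantile trends

For τ ∈ {0.15, 0.50, 0.85}, the model minimizes the check loss
Σ ρ_τ(dᵢ − a − b·yearᵢ) over first-capture days dᵢ.  Years are centered
before fitting (conditioning); slopes are surfaced only as days per
decade (10·b), and the intercept is the fitted day at the mean observed
year.

**Solver.**  The fit solves the exact LP in its dual form (n variables,
two equality constraints; HiGHS), recovering (a, b) from the equality
duals, with a fallback reconstruction through the basic observations.
An optimal line always passes through at least two sample points, so a
pairwise-enumeration oracle gives the exact minimum for moderate n; the
solver is held to that oracle at 1e-8 relative tolerance in the tests.

**Ties.**  Day-resolution data can produce a flat optimal face (several
lines with identical loss).  Two secondary LPs then select the
lexicographically smallest (slope, intercept) vertex, followed by a
vertex-snapping step that removes the LPs' feasibility-slack noise by
re-deriving the line exactly through its supporting points.  The
refinement LPs scale poorly (seconds at n ≈ 3,000), so the default
`tie_break="auto"` applies them only up to n = 2,000 and otherwise
returns the solver's vertex; the result is deterministic at every n,
which is what the tie-break exists to guarantee.

**Bootstrap.**  Uncertainty comes from case resampling of (year, day)
pairs, 1,000 replicates and percentile 95% intervals by default, with
all quantiles refit on each replicate so that the 0.85−0.15 contrast is
computed within replicates and its interval respects the correlation
between tail slopes.  Replicates whose resampled years are all
identical are redrawn (capped at 10× the replicate count).  For
replicates with n > 2,000 an iteratively-reweighted fit followed by the
same vertex-snapping is used; its objective agrees with the exact LP to
~1e-10 relative at that scale, and snapping makes exact ties (e.g. a
slope of exactly 0) come out exact rather than within float noise.
Bootstrap standard deviations are reported alongside the intervals and
labeled as bootstrap SDs.

**Scenario classification.**  A significantly positive contrast is an
expansion of passage duration; significantly negative, a contraction;
otherwise a significant trend in either tail is a parallel shift, and
nothing significant anywhere is no change.  Significance means the 95%
interval excludes zero; no multiplicity correction is applied across
species or quantiles.

Empirical passage duration is the 0.85 minus 0.15 quantile of pooled
first-capture days, with numpy's default linear interpolation (type 7).

## Stopover: hierarchical CJS

The likelihood conditions on first capture and marginalizes the latent
departure day through the χ recursion (χ_t = (1−φ) + φ(1−p)χ_{t+1},
χ_k = 1); an individual first captured at f and last seen at l
contributes φ^(l−f) p^d (1−p)^(l−f−d) χ_l with d its recaptures after
f.  This marginalized form was chosen over latent-state augmentation
because it is deterministic given parameters and can be verified
against exhaustive enumeration of departure days (the tests do both
this and the sum-to-one check over all continuation histories).  The
per-matrix sufficient statistics (total spans, recapture counts,
individuals per last-capture occasion) make one evaluation O(k).

Hierarchy: logit φ_y and logit p_y are exchangeable normal draws around
hyper-means μ_φ, μ_p (prior N(0, variance 1000) — the mean/precision
notation N(0, 0.001)) with SDs σ_φ, σ_p ~ Uniform(0, 5).  Years with no
individuals contribute no likelihood and are drawn from the
hyperdistribution.  Estimates for sparse years shrink toward the pooled
mean, so fitted stopover trends are conservative.

**Sampler.**  Adaptive random-walk Metropolis-within-Gibbs: year-level
parameters and the σs get scalar normal proposals whose scales adapt
toward 44% acceptance during burn-in (frozen afterwards, preserving
detailed balance in the retained draws); the hyper-means are conjugate
normals and are drawn exactly.  The default schedule is 3 chains ×
30,000 iterations, burn-in 10,000, thinning 3 ("retain a third"
interpreted as thin = 3 after burn-in).  Initial values are pooled
moment-style estimates (p from recaptures per occupied day; φ from the
geometric span/cohort relation), clipped to [0.05, 0.95], with up to 10
jittered re-initializations if the likelihood is non-finite.

Convergence is the classic Gelman–Rubin R-hat (between/within-chain
variance ratio; formula in the docstring), with threshold 1.05;
effective sample sizes come from arviz.  R-hat is hand-implemented so
the classic formulation is explicit, and is cross-checked against
arviz's identity-method R-hat in the tests.

**Transform.**  Stopover duration is −1/ln φ (continuous-time life
expectancy), strictly increasing in φ.  Annual summaries report the
posterior median and central 95% interval of the transformed draws; by
monotonicity the median commutes with the transform (asserted in tests
rather than assumed).  Note the discrete-day mean stay in the simulator
is 1/(1−φ), not −1/ln φ (≈ 2.5 vs ≈ 1.96 at φ = 0.6); recovery tests
compare estimates with the transform of the true φ, i.e. like with
like.

## Trend comparison

Annual stopover medians are regressed on year by unweighted OLS
(posterior interval widths are carried in reports but not used as
weights — a known limitation); slopes are ×10 to days per decade.  With
one predictor the type II analysis-of-variance F equals the ordinary
regression F and F = t².  A constant series is reported as slope 0,
F = 0, p = 1 rather than a 0/0 ratio.  Passage-change and stopover
rates are paired by species-season (pairs missing a fitted model on
either side are dropped and listed), correlated with Pearson's r
(two-sided t-based p), and summarized by identity-line residuals, a
sign-concordance table, and the ratio of mean absolute rates.

## Synthetic data

The generator emulates a constant-effort mist-netting study:

* **Arrivals.**  Per-year cohorts draw arrival days by inverse-CDF
  sampling from a piecewise-linear quantile function through
  (0.15, q15), (0.50, q50), (0.85, q85) with linear tails through
  (0.02, q15−(q50−q15)) and (0.98, q85+(q85−q50)), then round to
  integer occasions and clip to [1, k].  The construction makes the
  three target quantiles — the exact quantities the phenology model
  estimates — directly controllable and linearly drifting in days per
  decade.  Parameter sets whose quantile curves would cross anywhere in
  the simulated span are rejected up front with the offending year
  named.
* **Stays and detection.**  Geometric residence (daily persistence
  φ_y), matching the CJS constant-φ assumption; daily Bernoulli(p_y)
  detection.  Year effects act on the logit scale (optionally with a
  linear logit-scale trend in φ), which keeps every realized
  probability inside (0, 1) by construction.  The default logit-scale
  year-effect SDs are 0; recovery studies in the tests use values
  within the 0.006–0.355 range typical of year-to-year variance in this
  setting.
* **Conditioning.**  Individuals never detected are discarded — real
  banding data cannot contain unobserved birds, and the CJS likelihood
  conditions on first capture.  Truth tables retain all individuals
  with a detected flag so conditioning itself is testable (e.g. with
  one-day stays the retention rate equals p).
* **Defaults.**  46 years and cohorts of ~1,000 individuals per year
  reflect the multi-decade, 300–7,500-individuals-per-species scale of
  the motivating data; φ ≈ 0.6 and p ≈ 0.3 give stopovers of ~2 days
  and realistic recapture fractions.
* **Seeding.**  One master seed; per-year streams are spawned
  deterministically, so year y's draws do not depend on other cohorts'
  sizes.  Seeded runs are bit-reproducible.

Not emulated: net-closure gaps (all k occasions are sampled every
year), within-season variation of φ or p, age/sex structure, weather
covariates, multi-site movement, and right-censoring at season end
(birds present at occasion k simply stop being observable; no
correction is applied).  Passing recovery tests therefore show the
estimators are correct under their own assumptions, not that real data
satisfy those assumptions.

## Problem sizes in tests and the acceptance script

Exact checks (window arithmetic, recapture percentages, hand
likelihoods, normalization on k ≤ 6, transform values) are instant.
The solver oracle uses 50 random datasets with n ≤ 200.  CJS recovery
uses 10 years × 500 individuals at k = 20 with 3 chains × 6,000
iterations (a reduced schedule; the full default is 30,000).  Phenology
recovery uses 46 years × 1,000 arrivals with 200 bootstrap replicates.
Replication studies (bootstrap coverage, posterior-interval coverage,
the end-to-end comparison) run at deliberately smaller sizes — tens of
replicates of a few thousand observations — chosen so each property is
statistically decidable; assertions there use bands wide enough to
absorb the Monte-Carlo noise at those sizes.

## Known limitations

* The random-walk sampler mixes more slowly than gradient-based
  samplers for strongly correlated posteriors; R-hat and ESS are
  reported so users can judge.
* Unweighted OLS on annual medians ignores the posterior uncertainty
  of each year's estimate.
* The overwinter-removal rule is a definition, not an inference; its
  output should be reviewed when applied to a new station.
* Percentile bootstrap intervals can undercover slightly at small n or
  extreme τ.
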