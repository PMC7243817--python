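# stopover

Tools for asking two linked questions about songbird migration at a
long-running banding station, and for testing whether the answer to the
second explains the first:

1. **How is migration timing changing?**  Trends in the 0.15 / 0.50 /
   0.85 quantiles of first-capture date versus year, fit by quantile
   regression.  The derived contrast — slope of the 0.85 quantile minus
   slope of the 0.15 quantile — is the rate of change of **passage
   duration**: the number of days per season a species occupies the
   site.  Diverging tails widen passage, converging tails shrink it.
2. **Is stopover duration changing?**  A hierarchical Bayesian
   Cormack–Jolly–Seber (CJS) model estimates each year's daily
   persistence probability φ and recapture probability p from binary
   capture histories, conditioning on first capture.  Expected
   **stopover duration** (length of stay after first capture) is the
   life-expectancy transform −1/ln φ.

Because mist nets sample only a fraction of birds present each day,
longer stopovers raise the chance an individual is seen at all and so
widen the observed spread of first captures — the mechanistic route by
which stopover change *could* drive passage change.  The package closes
the loop by regressing annual stopover estimates on year and comparing
the two rates (both in days per decade) on a 1:1 axis.

The intended users are analysts of constant-effort banding/ringing data
who want these two pillars as tested, scriptable model objects rather
than one-off scripts.

## Models

Quantile trend for level τ: minimize Σᵢ ρ_τ(dᵢ − a − b·yearᵢ) with check
loss ρ_τ(u) = u(τ − 𝟙[u<0]); slopes are reported as 10·b (days/decade).
The fit solves the exact linear program; uncertainty is case-resampling
bootstrap (percentile intervals, contrast computed within replicates).

CJS likelihood, constant (φ, p) within a season, marginalized over the
latent departure day with χ_t = (1−φ) + φ(1−p)χ_{t+1}, χ_k = 1.  Years
share logit-normal random effects: logit φ_y ~ N(μ_φ, σ_φ²), logit p_y ~
N(μ_p, σ_p²), with diffuse N(0, variance 1000) hyper-mean priors and
Uniform(0, 5) priors on the logit-scale SDs.  Sampling is adaptive
Metropolis-within-Gibbs (3 chains × 30,000 iterations, 10,000 burn-in,
thinning 3 by default) with classic Gelman–Rubin R-hat diagnostics.

A synthetic-data module generates banding records with known ground
truth (drifting arrival quantiles, geometric stays, Bernoulli
detection, never-detected birds discarded) so every stage has a
parameter-recovery test.

## Worked example

```python
import stopover as so

# 30 years of spring banding for one synthetic species: the late tail
# of the arrival distribution delays by 1.5 d/decade while the early
# tail is stationary, and stopover behaviour does not change.
arr = so.ArrivalTrendParams(baseline_quantiles=(10, 20, 30),
                            slopes_per_decade=(0.0, 0.75, 1.5),
                            n_years=30, cohort_size=400,
                            season_length_k=so.SPRING.k)
stay = so.StopoverDetectParams(phi_mean=0.6, p_mean=0.35, phi_logit_sd=0.15)
records, truth = so.simulate_banding_dataset(arr, stay, seed=11, species="SYN")

prepared = so.preprocess(records)
first = so.first_captures(prepared)

phen = so.PhenologyTrendModel.from_first_captures(
    first, "SYN", "spring", day_column="occasion").fit(n_boot=500, seed=12)
print(phen.summary())
```

```
Quantile trends — SYN spring
============================
n = 6772 first captures, bootstrap n_boot = 500 (percentile CIs)

        quantity  slope d/dec               95% CI sig
        tau=0.15        0.000 [  -0.703,    0.556]
        tau=0.50        0.714 [   0.000,    1.154]
        tau=0.85        1.176 [   0.540,    1.776] *
  passage change        1.176 [   0.500,    2.000] *

scenario: expansion
```

The late tail's delay is detected (+1.18 d/decade, CI excluding 0; the
simulated truth of +1.5 is inside the CI), the early tail is flat, and
the passage-duration contrast correctly classifies the dataset as an
*expansion*.  Continuing with the stopover pillar:

```python
histories = {y: m for (_, _, y), m in so.build_capture_histories(prepared).items()}
cjs = so.HierarchicalCJSModel(
    histories, so.CJSConfig(iterations=6000, burn_in=2000)).fit(seed=13)
print(cjs.summary())

trend = so.stopover_trend(cjs.annual_stopover(), species="SYN", season="spring")
print(f"stopover trend: {trend.slope:+.3f} ± {trend.se:.3f} days/decade "
      f"(F = {trend.F:.2f}, p = {trend.p_value:.3f})")
```

```
Hierarchical CJS — SYN spring
=============================
years: 1970–1999 (30), individuals: 6772
chains: 3, retained draws/chain: 1333
pooled phi (inv-logit mu_phi): 0.601   pooled p: 0.333
pooled stopover -1/ln(phi): 1.96 days
max R-hat: 1.0343 (< 1.05)

stopover trend: -0.015 ± 0.038 days/decade (F = 0.15, p = 0.706)
```

The model recovers the simulated persistence (φ = 0.601 vs truth 0.60;
p = 0.33 vs 0.35), converges (R-hat < 1.05), and finds no stopover
trend — exactly the simulated condition in which passage duration
expands for reasons other than stopover change.  With several
species-season datasets, `stopover.compare_trends` correlates the two
rate sets and `stopover.write_report` renders the summary tables,
forest plots and the 1:1 scatter.

A `stopover` command-line tool wraps the same stages
(`simulate`, `preprocess`, `phenology`, `cjs`, `compare`); see
`stopover --help`.

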