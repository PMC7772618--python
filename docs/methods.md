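# Methods

This note records the models implemented in `popenergy`, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic-data tests do and do not demonstrate about field data.

## Per-bear energetics

Body mass is estimated from straight-line body length *L* (cm) and
axillary girth *G* (cm) with a class-specific log-linear allometry,
ln *M* = b₀ + b_g ln *G* + b_l ln *L* (kg). Lean (structural) mass uses a
cubic length allometry *M*_str = c (*L*/100)³ with c = 14.9 kg m⁻³, the
isometric scaling standard in mammalian body-composition models. Storage
mass is *M* − *M*_str; storage energy multiplies storage mass by the
energy content of reserve tissue, φ_lip·39.3 + φ_pro·17.8 MJ kg⁻¹, where
φ_lip and φ_pro are the class-specific lipid and protein mass fractions
of storage (the remainder is water). Energy density divides storage
energy by lean mass.

**Constants are data, not code.** They ship in
`src/popenergy/data/energetics_params.yaml` with a provenance field and
can be overridden wholesale. The shipped defaults are *synthetic*:
structure-faithful and numerically realistic (adult males ~400 kg and
holding the most total storage; solitary adult females with the most
lipid-rich, hence most energy-dense, reserves; dependent young the
leanest) but not transcribed from field-calibrated coefficient tables.
Any field application must replace them with published class-specific
values.

**Emaciated bears.** When estimated body mass falls below structural
mass, storage is floored at 0 with a logged warning — storage energy is
a non-structural reserve and cannot be negative. The identity
energy_density × lean_mass = storage_energy holds exactly for every
profile, including at the floor.

## Sea-ice phenology

Breakup: first spring ordinal date with region-mean concentration ≤ 50%
for three consecutive days. Freeze-up: first autumn date ≥ 10% for three
consecutive days. Open water: freeze-up − breakup − 25 days (bears come
ashore ~3–4 weeks after breakup). Implementation decisions:

- The *first* day of the qualifying run is returned, matching the
  "first ordinal date … for three consecutive days" definition.
- Search windows default to day ≥ 60 (breakup) and ≥ max(breakup+3, 213)
  (freeze-up) to keep mid-winter noise from triggering false events;
  both bounds are arguments.
- A missing day terminates a run; ≥ 20% missing days inside a search
  window logs a data-quality warning.
- Ordinal dates are used as-is in leap years (≤ 1-day artifact).
- Per-cell input is averaged per day before thresholding; the threshold
  applies to the regional mean, not per cell.

Winter indices: AOw = mean Jan–Mar of year *y*; NAOw = mean December of
*y*−1 through March of *y* (December attributed to the winter it opens,
so the first year of a series has no NAOw). Lag-1 covariate columns are
only filled across consecutive years.

## Demographic classes

Seven classes: adult male (≥ 5 y), solitary adult female (≥ 5 y), adult
female with offspring, subadult male/female (2–4 y), yearling (1 y), cub
(0 y). Ages are as recorded at autumn capture with no birthday
correction (autumn-only sampling makes this safe). Offspring status is
taken from the record; mothers are not inferred from accompanying cub
records. Cubs and yearlings classify without sex; from age 2 a missing
sex is an error.

## Population energy estimator

Six stages per outer replicate and year: (1) for each class, resample
with replacement from the yearly class percentages in the five-year
window centred on the year, average, repeat B₁ times and average the
bootstrap means; (2) draw bears onshore from Normal(N̂, SE); (3) multiply
proportions by the draw; (4) for each class, bootstrap the mean per-bear
energy (density and storage jointly) from the class-year's profiled
captures with B₂ iterations; (5) multiply counts by mean energies; (6)
sum over classes. The reported annual estimate is the mean over R outer
replicates, its SE the SD of replicate totals (the Monte-Carlo analogue
of a standard error of the mean). Defaults: window 5 years,
B₁ = B₂ = 2000, R = 10,000.

Numerical and design decisions:

- **Bootstrap-average identity.** The mean of B resample means of n
  values depends only on the pooled resample counts, which follow
  Multinomial(B·n, uniform). The implementation draws those counts
  directly and applies them as weights — *exactly* the same distribution
  as the literal B-iteration loop, at a tiny fraction of the cost; the
  full default replication runs in seconds. Dividing by the total after
  the weighted sum keeps constant-value pools exact (a cell of identical
  bears has zero bootstrap variance to the last bit).
- **Window truncation** at the series edges (the first year uses the
  first five years), keeping an estimate for every year rather than
  dropping edge years.
- **Abundance truncation at zero** by redraw; negative bear counts are
  meaningless. With SE = 0 the draw is the point estimate.
- **Renormalization** of the class-proportion vector after classwise
  bootstrap averaging, since classwise resampling does not preserve the
  unit sum.
- **Empty class-year cells** fall back to pooling that class over the
  five-year window (logged); if the pool is still empty while the class
  has a nonzero share, the year is reported as missing (NaN row), never
  a crash. A class entirely absent from the window contributes zero.
- **Fractional counts** are kept; the totals are expectations, not
  integer censuses.
- **Reproducibility.** A master seed spawns one deterministic stream per
  (year, stage) via `SeedSequence(seed, spawn_key=...)`, with
  replicate-indexed draws inside each stream, so results are independent
  of execution order and identical across runs; within-pool values are
  sorted canonically so input row order cannot change the output.
- "Population energy density" follows the summed-over-bears convention
  (MJ kg⁻¹ totalled across the population). It is *not* an intensive
  quantity; it scales with abundance by construction.

## Trend and environment models

- OLS fits via statsmodels with AIC = −2ℓ + 2k, k counting intercept,
  slopes and the residual variance.
- The smooth trend candidate is a penalized cubic B-spline (basis
  dimension 10) delegated to statsmodels' GLMGam; the penalty weight is
  chosen by a GCV grid (10⁻⁴–10⁸), and the effective degrees of freedom
  are the trace-based total minus the intercept (edf = 1 ≈ linear; at
  very large penalties the fit reproduces the straight line within
  tolerance). The smooth log-likelihood is recomputed from the RSS in
  the same concentrated-Gaussian form as the OLS fits so the two AICs
  are directly comparable. ΔAIC < 2 keeps the simpler (linear) model;
  smooth non-convergence falls back to linear with a warning.
- Class-level environment models use a random intercept per bear ID
  (statsmodels MixedLM, fitted by ML so AICs compare across fixed
  effects); data without repeated individuals degrade to OLS, which the
  degenerate case reproduces to ~1e-6.
- The a-priori covariate menu defaults to every singleton and pair of
  {breakup, open water, AOw, NAOw and their one-year lags}; candidates
  containing a pair with |Pearson r| > 0.6 on the fitted data are
  removed. Pairs with an undefined r (constant column) are inadmissible.
- Class differences use Kruskal–Wallis (tie-corrected, scipy) with
  Dunn's pairwise z tests implemented from the standard rank-sum
  formulas with tie correction; multiplicity is Holm-adjusted.
  Significance threshold α = 0.05 throughout.
- Scenario prediction evaluates the stored linear predictor; the
  published WH coefficient sets (energy density and storage energy on
  breakup date + lagged open-water period) ship as reference fits with
  their printed SEs, R², and F statistics.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the study system with
configurable truth: Poisson capture counts around 128/year; the observed
class mix; repeat captures with probability 0.41 (≈ 1.7
captures/individual); per-class storage-energy distributions with a
configurable per-decade drift (default: −232 MJ/decade for solitary
adult females, 0 elsewhere so the ground truth stays interpretable);
breakup starting at day 183 advancing 5.5 days/decade and freeze-up at
day 313 retreating 4.3 days/decade (open water 105 days in the first
year); abundance declining linearly from 1200 at 11.5 bears/year with
constant SE 150; white-noise monthly climate indices.

Morphometrics are generated by inversion: each bear receives a target
storage energy and a length draw, and the girth is solved in closed form
from the mass allometry so the energetics chain recovers the target
exactly. The seasonal ice curve is a double logistic whose midpoints are
back-solved so the threshold rules fire exactly on the configured dates
at zero noise (detected dates are the integer ceiling of the configured
real-valued dates).

Not emulated: spatially explicit ice fields, individual movement,
capture-probability heterogeneity, family structure (offspring are class
labels only), age-dependent morphometrics within a class, and any
correlation between body condition and capture probability. Passing
tests therefore demonstrate the *estimator's* correctness and
calibration under known truth — not that the synthetic distributions
match WH field data.

## Problem sizes used in tests

Unit and property tests run on 6–12-year scenarios at 20–60
captures/year with reduced replication (inner bootstraps 20–200, outer
replicates 100–2000); the closed-form SE check uses the full 10,000
outer replicates, and parameter-recovery tests use the full 34-year
span. These sizes give Monte-Carlo errors far below every assertion
tolerance while keeping the whole suite fast.

## Known limitations

- The shipped energetics constants are synthetic defaults (above); all
  absolute energy values computed with them are illustrative.
- Solitary females cannot be split into pregnant and non-pregnant; the
  class model inherits that ambiguity from the field protocol.
- The estimator treats annual abundance estimates as independent
  normals; any sampling covariance between years is ignored.
- GCV can select a mildly wiggly spline on short pure-noise series; the
  ΔAIC < 2 rule usually, but not always, returns such cases to the
  linear model.
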