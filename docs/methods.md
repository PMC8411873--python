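# Methods

## Scope and model

The package analyses a *scenario pair*: two gridded simulations of the
same year that differ only in whether fire emissions are included.  All
fire attribution is by subtraction — exposure differences cell by cell,
burden differences stratum by stratum (M_FIRE = M_ALL − M_FIRE_OFF).
Negative differences are retained (fires can suppress ozone production
locally); for PM the generator guarantees a nonnegative fire
contribution by construction.

### PM2.5 exposure-response (GEMM)

RR(z) = exp(θ·log(1 + z/α)/(1 + exp(−(z − μ)/ν))), z = max(0, C − cf).
The packaged default is the all-age NCD+LRI aggregate
(θ = 0.1430, SE 0.01807, α = 1.6, μ = 15.5, ν = 36.8 μg m⁻³), with a
five-cause table (IHD, stroke, COPD, lung cancer, LRI) available behind
the `gemm_variant` switch; both are configuration inputs, replaceable
by CSV, not constants of the code.  The counterfactual cf defaults to
2.4 μg m⁻³, the curve's low-concentration cutoff, and is exposed in
config.  For θ ≥ 0 the curve is monotone nondecreasing and RR = 1 at or
below cf; both properties are tested on dense grids.

### Ozone exposure-response

Long-term respiratory mortality responds log-linearly to the annual
average daily-maximum-8-h concentration (ADM8h):
RR = RR₁₀^(max(0, ADM8h − TMREL)/10).  Defaults RR₁₀ = 1.12 (95% CI
1.08–1.16) and TMREL = 26.7 ppbv are the values most commonly used with
this functional form in the cohort literature; both are plain config
fields because published assessments vary in the threshold they adopt.
The 8-hour windows are confined within calendar days (17 windows, start
hours 0–16); a `cross_day` flag enables midnight-spanning windows.
Days with fewer than 8 valid hours are excluded; cells with no valid
day are missing.

### Burden and uncertainty

Burden per cell/cause/age = AF·rate·age_fraction·population with
AF = (RR − 1)/RR, aggregated over region masks (declarative lat/lon
boxes or polygons).  Baseline rates may be supplied per region and are
broadcast to cells via the masks.  DALYs use the same attributable
fraction applied to baseline DALY rates — no life-table modelling.

95UIs are Monte Carlo (default 1,000 draws): θ ~ Normal(θ, SE);
baseline rates lognormal with median at the central estimate and σ
matched to the 95UI; age fractions logit-normal.  One draw set is
sampled up front and reused for every scenario, region and metric, so
the subtraction-method interval is a per-draw difference and group
intervals are per-draw sums.  Endpoint-summed intervals are provably at
least as wide under this scheme, which is why the reported group UIs
are never wider than the sum of member UIs.  Central estimates always
use central inputs (not draw means).  With all input uncertainties
zero, every interval collapses to the central estimate exactly.

### Model evaluation

Fire-derived PM at a station is the monthly series minus that calendar
year's minimum monthly mean (each year independent; years with < 2
valid months are flagged missing).  The operation is idempotent and
maps the minimum month to zero; when the minimum month truly carries no
fire signal it recovers the fire contribution exactly, which is the
basis of the isolation test.  NMBF follows the symmetric two-branch
definition (Σm/Σo − 1 when the model mean is high, 1 − Σo/Σm when low);
it is antisymmetric, scale-invariant, and equals b − 1 for a pure
multiplicative bias b ≥ 1.  Stations are mapped to their containing
grid cell by default (bilinear sampling by config).  Multi-station
composites are unweighted means per timestamp; composite metrics and
averaged per-station metrics are different statistics and are not
asserted equal.

### Equity analysis

Cell-level (not population-weighted) statistics are the default for
IMR-binned summaries, matching the gridded-value convention; a
population-weighted mean is available by passing the population grid.
Bin and class intervals are left-closed right-open, with the final bin
right-closed — this also resolves the boundary overlap in the published
poverty-class scheme (IMR 32 belongs to "poor").  The extreme-group
comparison (defaults IMR ≤ 20 vs ≥ 60 at 99% confidence) uses Welch's
unequal-variance t-test; the literature this mirrors names no test, so
the choice is recorded here, and a seeded permutation test is provided
as an exactly-calibrated alternative.  On the generator's right-skewed
fire-PM fields the Welch test is very slightly anti-conservative
(empirically ≈1.2% rejection at α = 1% over 3,000 replicates, inside
the binomial 95% margin) — acceptable for the screening use it serves.

## Synthetic study conditions

The generator emulates a Southeast-Asia-like premonsoon burning season
on a 10° × 10° domain at 0.25° (40 × 40 cells), 12 months, 365 days of
daily-max-8-h ozone, 12 monitoring stations:

- **Fire signal**: Gaussian plumes in space (amplitudes 30–55 μg m⁻³
  PM2.5 at centre, decay 160–220 km), triangular in time over
  January–May peaking in March; zero outside the season.  PM10 scales
  the fine fire signal by 1.15; the background by 1.7.
- **Background PM2.5**: mean 16 μg m⁻³ with a linear gradient toward
  the urbanised southeast corner, so nonfire pollution anti-correlates
  with the remote fire-prone uplands — the configuration under which a
  poverty proxy coupled to fire PM reproduces the observed opposite
  disparities for fire and nonfire exposure.
- **Ozone**: background 35 ppbv with a ±6 ppbv seasonal cycle peaking
  with the fire season, plus a fire enhancement of up to 6 ppbv
  following the plume pattern.
- **Population**: 80 million in Gaussian urban clusters (75%) plus a
  noisy rural floor (25%), normalised to the exact total.
- **IMR**: base 35 + 3.0 per μg m⁻³ of fire-derived PM2.5 + N(0, 12),
  clipped to [0, 100].  The coupling coefficient is the ground-truth
  dial for disparity tests: 0 gives independence (used for type-I
  calibration), positive values give a known gradient.
- **Noise**: mean-one lognormal multiplicative on concentration fields
  (σ = 0.08 monthly, 0.05 daily ozone) keeps positivity and preserves
  all ≥ nofire, since background and fire components are perturbed
  separately and added.  Station observations are bias × model + N(0,
  3 μg m⁻³), bias 1.25, so the model "underestimates" by a factor
  ≈ 1.25 and evaluation metrics have known targets.
- **Streams**: every product draws from its own RNG stream derived from
  the master seed by fixed offsets; adding a product never perturbs the
  others, and equal seeds give bit-identical outputs.

What the generator does **not** emulate: emission inventories,
meteorology, chemistry, interannual variability, long-range transport,
or realistic absolute magnitudes of population and baseline rates.
Passing tests therefore demonstrate the correctness and calibration of
the analysis machinery under controlled conditions, not the accuracy of
any real-world burden estimate.

## Numerical choices

- Annual means are derived from monthly fields on demand, so
  "annual = mean of months" is exact.
- Threshold exceedance uses strict ">" ("above" a guideline).
- Percentage change is 100·(with − without)/with, missing where the
  all-sources value is nonpositive.
- Regional means are population-weighted by default; a cos(latitude)
  area weighting is available for non-population metrics and is off by
  default because reported quantities are population-weighted.
- Presentation rounding (PM mortality/DALYs to nearest 100, ozone
  mortality to nearest 10, half away from zero) is applied last;
  machine-readable outputs always carry unrounded values, and group
  totals equal member sums before rounding by construction.
- Burden computations vectorise the Monte Carlo as
  (draws × cells) attributable-fraction matrices per cause; at the demo
  size (1,600 cells, 1,000 draws) the full pipeline runs in seconds.
- The example "SE China" mask rule in configs uses 98°E as the western
  bound (the widely-quoted "east of 98°W" is treated as a typo).

## Known limitations

- No PM toxicity differentiation by source; fire and nonfire PM2.5 are
  assumed equally harmful.
- No conservative-area regridding (bilinear and block-mean only) and no
  map projections beyond regular lat-lon.
- DALY attribution inherits every assumption of the mortality pathway.
- The IMR poverty proxy analysis is descriptive; no causal claims.
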