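# Methods

## The estimator

The model predicts a daily humidity variable at a point as the sum of a
spatial interpolation baseline and a learned correction:

```
ŷ(x, d) = IDW(x, d) + f(z(x, d))
```

where `IDW(x, d)` is the inverse-distance-weighted mean of same-day station
values, `z` is an 18-slot predictor vector, and `f` is a gradient-boosted
ensemble of regression trees fit to the residual `y − IDW` with a
squared-error objective. The residual framing encodes a strong prior: the
station network itself is the best single predictor of humidity, and the
trees only explain what interpolation leaves over (grid-product biases,
covariate effects at scales the network cannot resolve, conditions where
interpolation degrades such as isolated stations). A consequence worth
knowing: the IDW term enters with an implicit coefficient of 1, so the
design pays off exactly when interpolation is strong. When a gridded
predictor is *more* accurate than the network, a linear blend of the two
can beat the residual design at small sample sizes, because tree splits
approximate the needed subtraction of two continuous features poorly.

**IDW.** Distances are great-circle on a 6371 km sphere. The estimate is
`Σ dᵢ⁻ᵖ vᵢ / Σ dᵢ⁻ᵖ` over the k nearest in-radius neighbors; defaults
`p = 2`, `k = 8`, unlimited radius, recorded in model metadata (the method's
lineage does not pin these). Stations within 1 m of the query are treated
as coincident and averaged. Training rows always exclude their own station
("leave-self-out"); rows with no neighbor (single-station days) carry an
explicitly missing IDW feature and fall back to the training-mean DV as
baseline — the trees see the missingness and can react to it.

**Trees.** XGBoost with the tuned per-DV hyperparameters (T-min and mean:
500 rounds, depth 9, η 0.078, γ 0.38, λ 360, α 0.57; T-max: 500, 9, 0.051,
0.37, 120, 0.28); subsampling and column sampling are fixed at 1.0, the
base score at 0 (so a zero-round model is exactly the IDW baseline), and
fitting is single-threaded and seeded for bit reproducibility. Missing
feature values are passed to the learner natively.

## Dependent variables and cleaning

A study day is a midnight-to-midnight interval of fixed UTC−6. Records are
kept only when dew point and temperature are present and finite in the same
observation and the dew point lies within user-supplied record bounds
(defaults 210–310 K for synthetic work; no reference tables ship with the
package). Dew point is *not* forced below temperature: supersaturated
records are physically suspect but carry information, so they are counted
by a diagnostic rather than dropped.

The daily mean is a weighted mean with trapezoidal interval weights: each
observation carries half the gap to each temporal neighbor, and the first
and last observations additionally carry the gap to the day boundary capped
at 1 h (configurable), so a lone early or late reading cannot dominate.
With zero boundary cap this is exactly the trapezoid-rule integral of the
piecewise-linear series divided by elapsed time. T-min/T-max humidity take
the dew point at the earliest observation attaining the day's temperature
minimum/maximum. A station-day is kept when it has at least 4 observations
spanning at least 18 h (both configurable; the source lineage does not
state its completeness rule).

## Gridded predictors

Hourly fields are collapsed per cell to the quantity *analogous to the DV
being modeled*: the daily mean, or the value at the hour of the cell's own
temperature extremum (earliest hour on ties). Fine-grid gaps (typically
coastal) are backfilled from the nearest coarse-grid cell, with a per-cell
provenance mask. Column-water-vapor cells are discarded when the low three
QA bits equal 0b011 (a cloudy pixel); Terra and Aqua stay separate
features. All point lookups are nearest-cell-center (ties toward the lower
index), matching the per-cell semantics of daily raster products; no
bilinear smoothing is applied.

The 13-name static/calendar registry (longitude, latitude, elevation,
distance from water, population density, isolation, slope, vegetation
index, imperviousness, distance to urban center, water fraction within
10 km, day-of-year sine and cosine) is an explicit, serialized part of each
model artifact; predictions require the identical registry.

## Evaluation

Cross-validation is 5-fold by *station*: folds partition stations, every
row gets exactly one out-of-fold prediction, and the IDW feature of a
validation row is recomputed from training-fold stations only — reusing the
all-station feature would leak the held-out station's neighbors' geometry
advantage into the fold model. Metrics are the weighted RMSE, the weighted
SD of the observations (the no-skill yardstick), and bias. The default
weighting is inverse local density (weight ∝ 1/(1 + stations within 50 km),
normalized to mean 1) so dense metro networks do not dominate; uniform
weighting is available, and every report names its scheme. Subset
breakdowns: stations at least 12 km from every other station (unweighted),
and station-days with maximum temperature ≥ 92 °F (306.48 K, unweighted).

Two reference baselines run under the identical folds, per-fold IDW
features and weights: the IDW feature used directly, and OLS on the full
predictor vector with per-feature training-fold median imputation (OLS has
no native missing handling; the choice is documented, not inherited).

**Attributions.** Per-feature attributions use exact tree-path (Shapley)
attributions computed by the tree library itself; per row they sum with the
base value to the ensemble's residual output (verified to 1e-4 K before any
summary is reported). Summaries are means of absolute attributions,
overall and per region.

**Tuning.** Candidate hyperparameter vectors are drawn from a
maximin-optimized Latin hypercube (best of 100 random LHS designs by
minimum pairwise distance in the unit cube; integer parameters rounded, η
and λ sampled in log space). Each candidate's per-region-per-year weighted
RMSEs are standardized *across candidates* into z-scores (sample SD,
n−1 — the convention is stated in the output); candidates are ranked by the
mean and max of these z-scores plus fit time, and the final selection is
manual by design.

## Thermodynamics

Saturation vapor pressure uses the Bolton (1980) liquid-water curve
`e_s(T) = 611.2 Pa · exp(17.67 t / (t + 243.5))` (t in °C) at all
temperatures; no ice branch, keeping one consistent, invertible curve. Dew
point from specific humidity inverts this curve after
`e = q p / (ε + (1−ε) q)` with ε = 0.622. Relative humidity is
`100 · e_s(Td)/e_s(T)`, clipped at 100 % with a warning for supersaturated
input. The heat index follows the US NWS convention: the simple Steadman
average below 80 °F, otherwise the Rothfusz regression with the published
low-RH (RH < 13 %, 80–112 °F) and high-RH (RH > 85 %, 80–87 °F) adjustment
terms; all regime constants live in one table in the module. Parity is
claimed with the published formulas, not with any specific third-party
binary.

## The synthetic generator

The generator emulates the statistical structure the estimator assumes,
with every quantity a deterministic function of the configuration and its
seed:

- **Truth field.** Dew point = 290 K + a sum of eight random plane waves
  (narrow wavenumber jitter and near-equal weights; amplitudes normalized
  so the spatial SD equals `spatial_amp` exactly, and the wavenumber scaled
  so the empirical variogram range of the field equals `length_scale_km`)
  + a slow temporal harmonic + a mild diurnal cycle + covariate effects
  (elevation lapse −2 K/km; exponential drying with distance from the
  synthetic coast). Temperature adds a ≥ 2 K margin with a strong diurnal
  peak at 15:00, so the truth never supersaturates while noisy observations
  still can.
- **Observations.** Evenly spaced sub-daily sampling (default 8/day,
  symmetric to the day boundaries), Gaussian noise (default 1 K), and a
  configurable fraction of dew points removed to exercise cleaning.
- **Grids.** Fine hourly grids are truth at cell centers plus a smooth,
  time-constant spatial bias (the learnable error a reanalysis-style
  product carries); coarse grids are exact block means; a coastal band of
  fine cells is missing to exercise the fallback; the CWV proxy is a
  monotone transform of daily-mean dew point with noise and a random cloud
  mask in the QA bits.
- **Default conditions** (150 stations in an 8°×6° box, 30 days, 1 K
  noise, 160 km length scale): chosen so the network, not the grids, is the
  dominant predictor — matching the regime the residual design assumes, with
  plain-IDW cross-validation error near 1.7 K. Under these conditions the
  model's station-level CV RMSE sits near 1.3 K, approaching the noise
  floor from above. Across independent network/field realizations this
  figure varies by roughly ±0.3 K; tests evaluate the fixed default
  realization.
- **Nonlinear comparison scenario** (250 stations, 8 days, 6 K grid bias,
  a 3 K step effect of elevation at a 70 km terrain scale that the grid
  product does not resolve): constructed so that each estimator has a
  distinct failure mode — interpolation cannot see the sub-spacing step, a
  linear model captures only the step's linear shadow and cannot remove the
  curved grid bias, while the trees recover both. The expected ordering
  XIS < OLS < IDW-only then holds across seeded replicates. Few repeated
  days per station are deliberate: with many repeats, deep trees can
  memorize per-station corrections through lon/lat splits, which do not
  generalize to held-out stations.

What the generator does *not* emulate: real station metadata and QC flag
vocabularies, climatological realism of any particular region, spatially
correlated observation error, instrument drift, or reanalysis error
structures beyond a smooth bias. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline and the qualitative
behavior of the estimator — not the accuracy attainable on real archives.

## Numerical choices and degenerate inputs

Problem sizes throughout (desk-scale networks of 40–250 stations, 4–30
days) are chosen so the full suite cross-validates in minutes on one CPU.
Other choices: extremum and nearest-cell ties break toward the earliest
time / lower index; coincident IDW stations are averaged; a zero-variance
RMSE column yields z = 0 with a warning; an empty neighbor set is an
explicit missing feature, not an error; cleaning of an empty table returns
an empty table; single-observation days collapse all three DVs to that
observation (and are excluded by the default completeness rule); a
singular OLS design falls back to ridge with a warning.

## Limitations

Point predictions only — no per-prediction uncertainty. Years are modeled
independently; no temporal smoothing across days. Distances ignore earth
ellipticity (< 0.5 % error, immaterial under IDW smoothing). The spherical
IDW neighborhood does not respect coastlines or barriers. The evaluation
weighting scheme is a documented stand-in for the source lineage's
unspecified weights, not a claim of fidelity to it.
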