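# Methods

This document describes the downscaling method implemented by `marindown`,
the parameters it exposes, the synthetic test bed, and the numerical
choices made. Notation: `m(t)` a model series, `r(t)` a reference series,
`x(t)` any series to correct; `t` is fractional years (year + (month −
0.5)/12); fields are `(time, lat, lon)` arrays on regular lat/lon grids
with NaN for land/missing.

## 1. Grid operations (`marindown.grids`)

**Regridding** is bilinear interpolation between regular grids, with
NaN-aware weight renormalisation: at each target node the four surrounding
source values are combined with bilinear weights restricted to valid
(non-NaN) sources and renormalised; a node with no valid neighbour is NaN.
Target nodes outside the source bounding box are rejected (grids must
overlap). Renormalisation keeps output within the range of the
contributing values but slightly flattens gradients next to coastlines —
accepted because the alternative (NaN bleeding one cell inland) loses more
coastal ocean.

**Coarsening** averages `f × f` blocks of valid cells (`f` must divide the
shape); a block with no valid cell is NaN. This is the operator used to
place the fine reference on the working grid for the first correction
pass, so "coarse reference" and "coarsened reference" coincide by
construction.

**Gap filling** (`idw_extrapolate`) fills NaN target nodes from the `k = 4`
nearest valid source nodes with inverse-distance weights `1/d` on
great-circle distance (equirectangular approximation at these scales);
a coincident node copies the source value. Used after bilinear regridding
to extend the field to fine coastal cells that have no four-point support.

**Depth handling** (`DepthProfileStack`) stores per-level fields plus
bathymetry. Levels are masked only once the *previous* level is already at
or below the seafloor, so the first level below the seafloor is retained:
it is the bracketing value needed to interpolate the bottom value.
`interp_depth` interpolates linearly between levels (no extrapolation
above the first or below the last level); `extract_bottom` interpolates to
the bathymetric depth, clamping to the deepest valid level where the
bathymetry exceeds it.

## 2. Detrended quantile mapping (`marindown.dqm`)

Trained per cell and, by default, per calendar month (12 transforms per
cell), over an inclusive calendar-year `training_window`.

Training, additive mode:

1. **Scaling** `s = mean(r) − mean(m)` equalises the historical means.
2. **Detrending**: an ordinary-least-squares line is fitted to each scaled
   series; only the slope-anomaly `b·(t − t̄)` is removed, so detrending is
   mean-preserving. Missing values are ignored in the fit; a series with
   fewer than two valid points cannot be detrended and yields a flat
   (slope-0) model.
3. **Quantile adjustments** `A(p_k) = Q_{r̃}(p_k) − Q_{m̃}(p_k)` at
   `n_quantiles` probabilities `p_k = (k + 0.5)/n` (default `n = 100`).
   Quantiles use linear interpolation between order statistics at plotting
   positions `k/(n−1)` (numpy's default); the half-offset probability grid
   avoids pinning adjustments to the extreme order statistics.

Application to a series `x(t)` (historical or projection):

1. Scale by `s`, remove `x`'s own OLS trend anomaly, and re-centre on the
   trained historical level `c` (the mean of the scaled, trained model
   series). Re-centring matters for projections: their mean sits far above
   the training mean, and the adjustments are only defined on the trained
   distribution's support.
2. Interpolate `A` at each value's empirical position within the trained
   model quantiles (positions outside the trained range take the edge
   adjustment — constant extrapolation, the conservative choice for
   out-of-sample tails).
3. Add back the removed trend anomaly and undo the re-centring.

Because the trend over a 1993–2100 series is not one line, the series is
split at the end of the training window and each segment gets its own OLS
line (a single line through a trend-break would remove the wrong signal
from both segments). Within each segment the removed and re-added trend
cancel exactly, so the long-term change is preserved to rounding.

**Multiplicative mode** (strictly positive variables — oxygen,
chlorophyll): scaling is the ratio of means, detrending divides by the
trend line (ratio-to-trend), adjustments are quantile ratios, and the
corrected values are products — output positivity is structural. Mode is
selected per variable (`chlorophyll`, `oxygen` → multiplicative; others →
additive) and validated against the data sign.

**Gridded drivers**: `bias_correct(member, reference)` requires matching
grids (member vs coarsened reference); `downscale(corrected_fine,
reference)` runs the same machinery per fine cell after bilinear
regridding + IDW gap fill, which is what transfers the reference's
sub-grid spatial structure onto the projection. Land cells (all-NaN in
training) stay missing.

## 3. Ensemble statistics (`marindown.ensemble`)

Equal-weight member combination per cell and time step: mean, standard
deviation (population, `ddof = 0` — members are the population of the
constructed ensemble, not a sample from a larger one), and 2.5/50/97.5
percentiles with linear interpolation. A cell missing in *any* member is
missing in all statistics (an envelope computed over a varying member set
is not comparable across cells). Products are written as CF-styled NetCDF
with `n_members`, member identifiers and pipeline provenance as global
attributes; a missing provenance dict triggers a warning, not an error.

## 4. Evaluation (`marindown.evaluation`)

**Seasonal climatology**: per-cell means over DJF/MAM/JJA/SON months
within a calendar-year period (months assigned by calendar month, December
grouped with the following January/February's season label but selected by
month only — adequate at climatological averaging lengths).

**Skill**: for each season, over co-valid cells,
`alpha = mean(model)/mean(obs)`, `beta = std(model)/std(obs)` (population
std), `rho` = spatial Pearson correlation, and

```
LSE = 1 − sqrt((rho·alpha − 1)² + (beta − 1)²)
```

LSE = 1 is perfect agreement; the score is unbounded below. Temperature is
scored in Kelvin (offset 273.15) so that `alpha` is a physically
meaningful ratio rather than one that blows up near 0 °C. A constant
observed field (zero spread) or zero observed mean leaves the ratios
undefined and is rejected. The `mean` row averages each metric
arithmetically over the four seasons and recombines them; it is not the
LSE of a pooled field. `cos_lat_weights=True` enables cosine-latitude
area weighting of the spatial moments (off by default: the synthetic
domains span ~2° where weighting is a <0.1 % effect, and unweighted
moments keep the analytic test values exact).

**Observation matching** pairs point observations with the nearest product
grid node within a great-circle tolerance (default 100 m, equirectangular
distance) and a vertical tolerance (default 1 m) against the product's
nominal depth, restricted to the evaluation period; unmatched records are
dropped, and matching is order-independent. **Distribution overlap** is
the histogram intersection of matched model and observed values on a
common 20-bin range: 1 for identical samples, 0 for disjoint supports.

## 5. Uncertainty (`marindown.uncertainty`)

Changes are period-mean differences per cell: 2041–2060 ("mid-term") and
2081–2100 ("long-term") against the 1995–2014 baseline. Three ranges are
assessed on the ensemble-mean change fields:

- **Scenario uncertainty**: per-cell max − min of the change across
  scenarios (all models/members pooled per scenario first).
- **Model uncertainty**: per-cell max − min across models within a
  scenario, averaged over scenarios.
- **Internal variability**: per-cell max − min of the residuals of annual
  means about a centred 21-year running mean, computed on the interior
  years only (the first/last 10 years carry no residual, so a purely
  linear trend contributes exactly zero). 21 years is the conventional
  window separating interannual variability from forced decadal change.

`significance_ratio` returns |change| / uncertainty and a boolean mask
(ratio > 1). Zero-uncertainty cells are missing in the ratio (warned when
the change there is nonzero) and insignificant in the mask. `basin_series`
averages the ensemble statistics over a basin mask into annual series with
the 2.5–97.5 % envelope. Incomplete calendar years are dropped before any
annual averaging.

## 6. Synthetic test bed (`marindown.synthetic`)

All generators are seeded (`numpy.random.default_rng`, one independent
stream per (config seed, role tag)) and return the injected truth
alongside the data, so tests compare recovered against known quantities.

`SyntheticConfig` defaults (desk scale, one CPU, seconds per field):

| parameter | default | meaning |
|---|---|---|
| `fine_shape` | 24 × 24 | fine grid size |
| `fine_resolution` | 1/12° | fine grid spacing |
| `coarsen_factor` | 6 | fine→working ratio (4 × 4 coarse at 0.5°) |
| `hist_years` | (1993, 2020) | reference/training window |
| `proj_end_year` | 2100 | member end |
| `base_value` | 12.0 | domain-mean level (°C) |
| `large_scale_amplitude` | 3.0 | smooth N–S/E–W structure, resolved at both resolutions |
| `fine_scale_amplitude` | 1.0 | sub-grid pattern, present only in the reference |
| `seasonal_amplitude` | 2.0 | annual cosine cycle |
| `ar1_coef`, `noise_std` | 0.6, 0.5 | monthly AR(1) noise |
| `reference_trend` | 0.1 /decade | historical trend in the reference |
| `member_bias` | +2.0 | systematic member offset (constant or gradient) |
| `variance_inflation` | 1.5 | member noise-variance ratio vs reference |
| `scenario_trends` | 0.1/0.2/0.4 /decade | ssp126/ssp245/ssp585 post-2020 trends |
| `land_fraction` | 0.1 | land blob in the SW corner |

The reference is the fine pattern + seasonal cycle + historical trend +
AR(1) noise over the historical window. A member is the large-scale
pattern only (no fine structure), plus bias, inflated-variance noise, the
historical trend, and a scenario trend that starts at the first
post-historical year (piecewise-linear, continuous at the break).
`make_observations` samples the reference at grid nodes (optionally
displaced off-node by a controlled distance) with observation noise.
`expected_scenario_change` computes the injected change analytically from
the trend geometry for comparison with pipeline output.

Realism and limitations: the generator reproduces the failure modes the
method targets (bias, wrong variance, missing fine-scale structure,
scenario-dependent trends, coastal missing data) but is deliberately
simple — linear trends, stationary AR(1) noise, a time-invariant spatial
pattern, no trend in variance, no non-Gaussian tails, no
scenario-dependent pattern change. Conclusions about skill on these fields
bound the method's behaviour under its own assumptions; they do not
certify performance on real model output.

## 7. Pipeline and I/O (`marindown.pipeline`, `marindown.io`)

A YAML config (validated with itemised, key-by-key error messages; a
SHA-256 `config_hash` of the canonicalised config goes into product
provenance) drives the full chain: synth → regrid → bias-correct →
downscale → ensemble → evaluate → uncertainty, available as one `run` or
as stage subcommands on the `marindown` CLI (click). Each stage reads and
writes NetCDF, so stages can be rerun independently.

NetCDF is classic NETCDF3_64BIT via xarray's scipy backend (no
netCDF4/HDF5 dependency; 64-bit offsets avoid the 2 GiB classic limit).
Time is encoded as float64 days since 1900-01-01. Variables carry `units`
and `standard_name`-style attributes; reading requires units to be present
and rejects files with ambiguous multiple data variables. One quirk of the
scipy backend: global attributes become Python instance attributes on its
file object, so an attribute literally named `mode` breaks the writer —
the DQM transform files therefore store the mode as `dqm_mode`.

## 8. Design decisions

- **Hand-authored DQM core**: trend fitting, quantile estimation and the
  mapping itself are implemented directly (numpy primitives only) because
  the exact detrending/re-centring/segment-split semantics are the method;
  generic bias-correction libraries differ in precisely these choices.
- **Per-month training** (default) removes the seasonal cycle from the
  mapped distribution; with all months pooled, quantile adjustments
  conflate season with anomaly.
- **Constant-extrapolation tails**: values beyond the trained quantile
  range take the edge adjustment rather than an extrapolated one — robust
  for projections whose detrended values still drift past the training
  support.
- **Population statistics throughout** (`ddof = 0` in ensemble spread and
  skill `beta`): the quantities are descriptive moments of fully
  enumerated sets, not estimators of a parent population.
- **No area weighting by default** (see §4).
- **Equal member weights**: with synthetic members there is no performance
  basis for weighting, and equal weighting is the standard baseline.

## 9. Limitations

- Bilinear + IDW downscaling adds no information beyond the reference
  climatology; extremes sharper than the reference's historical
  distribution are not generated.
- DQM assumes the model's bias structure is stationary between the
  training window and the projection (the standard, untestable
  bias-correction assumption).
- The uncertainty partition uses min–max ranges, which grow with ensemble
  size and are noisier than variance-based partitions; with the small
  synthetic ensembles they are the only option that does not assume a
  distributional form.
- Monthly OLS trend estimates alias a seasonal cycle slightly (the cycle
  is not orthogonal to a linear ramp over windows that are not whole
  multiples of the cycle under the monthly sampling); the aliasing is
  identical before and after correction, so trend *preservation* is exact
  even though the estimated slope differs from an injected one by ~2 % at
  the default seasonal amplitude.
- Great-circle distances use the equirectangular approximation — accurate
  to well under a metre at the sub-kilometre matching tolerances and
  sub-degree domains used here, but not suitable for basin-scale
  distances.
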