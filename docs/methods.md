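# Methods

This note records the models, parameter choices and numerical conventions
behind `cropshift`, and what the synthetic test bed does and does not show.

## The emulation problem

The response is the crop-cover fraction of a grid cell, a value in [0, 1]
on a regular lat–lon grid. The emulator treats cover as an unknown, highly
nonlinear function of eight per-cell drivers — mean annual temperature (°C),
mean annual precipitation (mm yr⁻¹), an agro-ecological zone id
(categorical), normalised regional GDP, nitrogen and phosphorus fertiliser
application (kg ha⁻¹), dominant soil class (categorical), and elevation
(m) — and learns it with a bagged regression forest. Projection substitutes
climate-derived columns (annual means and the zone id) with their
perturbed-climate counterparts while the socio-economic and biophysical
layers are held static; the emulator is then simply re-evaluated.

## Regression forest

Each tree is a greedy binary CART: at a node, `mtry` candidate features are
drawn without replacement and the (feature, rule) minimising the summed
within-child squared deviation of the response is chosen; leaves predict
the mean response of their training rows. Growth stops when a node holds
fewer than 2 × `min_leaf` rows, the response is constant, or no candidate
split strictly reduces the error. Trees are grown on bootstrap samples of
*n* draws with replacement, so each tree sees ≈ 63.2 % distinct rows and
leaves ≈ 1/3 out of bag; "two-thirds in, one-third out" is only mutually
consistent under with-replacement sampling, which is why that reading was
adopted.

Defaults and conventions:

- `mtry = max(1, ⌊p/3⌋)` (the standard regression-forest convention) and
  `min_leaf = 5`. Both are configurable per protocol.
- Continuous splits test midpoints between distinct sorted values.
  Categorical splits search subsets of the levels present at the node —
  exhaustively for ≤ 10 levels, by mean-response ordering above that (the
  ordered scan is optimal for squared error). An unseen categorical level
  at prediction time follows the child that received more training rows.
- Tie-breaks are deterministic: lowest feature index, then lowest threshold
  (continuous) or smallest left-subset encoding (categorical), so a fixed
  seed reproduces a forest bit-for-bit.
- The ensemble prediction is the unweighted mean of tree outputs; the OOB
  prediction of a row averages only trees whose bootstrap never drew it.
  OOB R² is 1 − MSE_oob / var(y) over covered rows.
- %IncMSE permutes one feature's values within each tree's OOB rows,
  recomputes the OOB MSE and reports the increase as a percentage of the
  baseline OOB MSE. It is deliberately *not* scaled by a standard error,
  so absolute values are not comparable with implementations that do scale
  (rank order is). A constant column scores exactly 0.

## Training protocol

Training mirrors an iterated-subsample design: each of `n_iterations`
iterations draws `cells_per_iteration` distinct cells, splits them 70/30,
grows one tree on a bootstrap of the 70 % and records MSE/R² on the 30 %.
The pooled trees form the projection ensemble. Two error estimates are
reported side by side because they answer different questions: the mean
per-iteration holdout R² scores *single trees* (individually weak,
typically R² ≈ 0.7–0.85 here), while the pooled-ensemble OOB R² scores the
*averaged* predictor (≈ 0.95 on the default synthetic globe). Desk-scale
defaults are 200 iterations × 2000 cells on a 60 × 120 grid; larger
configurations (e.g. 1000 × 20 000 on a 360 × 720 half-degree grid) are
plain config changes.

Predictions are clamped (not rescaled) into [0, 1] at projection time;
since every leaf predicts a mean of training responses already in [0, 1],
clamping is a safety net, not a correction.

## Agro-ecological zonation

A zone id is the product of a thermal and a moisture regime, computed
per cell from the monthly climatology:

- Growing degree days: GDD = Σ_m max(0, T_m − 5 °C) × days_m, using monthly
  means as daily surrogates. Against a daily linear-interpolation oracle
  the monthly approximation agrees within 10 % on sinusoidal seasonal
  profiles (tested), which is adequate for classification into broad bands.
- Thermal regime, in order: polar/none where GDD < 150 °C·day; tropical
  where the coldest-month mean ≥ 18 °C; boreal where GDD < 1200 °C·day;
  temperate otherwise. The coldest-month *mean* stands in for "minimum
  temperature" (documented choice; absolute minima are not available from
  a monthly climatology).
- Moisture regime: monthly potential evapotranspiration by the Thornthwaite
  formula (heat index I, cubic exponent a(I); the day-length correction is
  omitted since the synthetic climatology already carries the latitudinal
  cycle). A month counts toward the growing period when T_m > 5 °C and
  P_m ≥ 0.5 × PET_m; the 0–12 month count is binned evenly into 3 ordinal
  classes. With 3 moisture classes there are 1 + 3 × 3 = 10 zone ids.

All thresholds live in config. They are deliberately documented as
*substitutes* in the spirit of classic global zonation schemes, not as any
published parameterisation — published AEZ parameter sets for this kind of
study are not reproducible from the open literature. Projected zones (PAEZ)
use the identical code path on the perturbed climatology, so baseline and
future zonation can only differ through the climate input. Uniform warming
never decreases GDD, and the tropical belt can only hold or expand —
both properties are tested.

## Change products

- Direction: +1 / −1 / 0 comparing projection with baseline at an explicit
  tolerance `tol` (default 0, so even a 0.01 → 0.01002 rise counts as
  positive; a 0.05 absolute filter ships as the `gt5pct` preset).
- Agreement across an ensemble: per cell, score = +n⁺ if positive votes
  outnumber negative, −n⁻ if the reverse, 0 on ties — unanimity over four
  members gives ±4. Cells where any member lacks data are NoData. The
  separate "zero cover in every projection" notion is exposed as its own
  mask (`all_zero_cover_mask`) rather than overloaded onto the tie score.
- Magnitude: (proj − base)/base, undefined where baseline is 0; zero-to-
  positive transitions are flagged as novel cover instead of reporting an
  infinite relative change. Ensemble magnitude averages the defined member
  values per cell; the novel mask is the union.
- Proportion summaries count up/down/same over cells with baseline
  cover > 0, excluding (and counting) NoData cells; the three proportions
  always partition the eligible set.

## Synthetic data

The generators emulate the statistical structure of global driver data,
not any real values: temperature falls from ≈ 26 °C at the equator to
≈ −22 °C at the poles with a seasonal cycle whose amplitude grows poleward;
precipitation has a wet equatorial band, dry subtropics and wetter
mid-latitudes, modulated by smooth seeded noise (annual totals span roughly
40–4000 mm yr⁻¹); land is contiguous blobs from a thresholded smoothed
random field; GDP is constant within 18 contiguous regions and normalised
to [0, 1] (the normalisation is an assumption — the convention used by the
original data is not published); soils are spatially autocorrelated
categories; fertiliser tracks GDP plus noise; elevation is a smooth
non-negative surface.

The generative cover function is known and recorded: a logistic squashing
of a latent suitability with a temperate optimum in temperature
(peak 16 °C, width 14 °C), a linear-saturating precipitation gain (scale
1500 mm yr⁻¹), additive GDP, soil and zone offsets, intercept −2.8, and a
floor of 0.08 subtracted and rescaled so genuinely marginal cells have
exactly zero cover (≈ 2 % of land cells), which gives novel-cover logic
something to detect. Gaussian noise (default sd 0.02) is added and
truncated — not resampled — to [0, 1], keeping the observed value monotone
in the latent one. These coefficients were fixed once, on the criterion
that the resulting cover field look like a plausible fractional land-cover
surface (mean ≈ 0.5, sd ≈ 0.25, full [0, 1] range, strongly precipitation-
driven); they were not adjusted afterwards.

What passing tests show — and what they do not: the synthetic globe
exercises every code path (mixed feature types, zone shifts, novel cells,
ensemble disagreement) and verifies that the pipeline recovers a known
surface and responds coherently to imposed perturbations. It does not show
that an emulator trained on real cropland data has any particular accuracy:
real drivers are collinear in ways the generators only partially mimic,
real GCM deltas have spatial structure these spatially uniform scenario
deltas deliberately lack, and real cover is far more zero-inflated.

## Scenarios

The default table is 4 pseudo-GCMs × 2 pseudo-RCPs: warming offsets
{1.8, 2.2, 2.6, 1.5} °C for the moderate-forcing analogue, doubled for the
high-forcing analogue, with member-specific precipitation factors
(0.96–1.14) chosen so the ensemble disagrees in sign in some regions, as
real ensembles do. Scenario deltas apply uniformly: temp + ΔT,
precip × factor, per month per cell.

## Numerical conventions and degenerate inputs

- NoData is IEEE NaN in memory; on disk, NaN for float layers and a −9999
  sentinel for integer layers (zone ids, agreement scores) in
  NetCDF3-classic files written through xarray.
- Grids are cell-centre registered, latitude descending from north; only
  plain lat–lon is supported, and nearest-centre resampling never blends
  values (categorical-safe).
- Empty bootstrap row sets, zero-tree forests, protocols larger than the
  data, non-monotone zonation thresholds, negative tolerances and grids
  that disagree are all rejected with explicit messages; a forest too small
  to give any row OOB coverage is an error rather than a silent NaN.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; repeated runs are bit-identical.

## Known limitations

- Single-tree holdout R² is intrinsically limited at the conventional
  `mtry = ⌊p/3⌋`: with 8 features, each split sees the informative ones
  with probability 1/4, so individual trees on ~1400-row samples plateau
  around R² ≈ 0.80 on the default globe. The pooled ensemble does not
  suffer from this (OOB R² ≈ 0.95); raising `mtry` trades ensemble
  diversity for single-tree strength.
- Regression only; no classification mode, and no proximity or
  tree-correlation diagnostics beyond OOB error and permutation importance.
- Fertiliser, GDP, soils and elevation are static across scenarios by
  design; no dynamic socio-economic futures.
- No reprojection between coordinate systems and no sub-monthly phenology;
  zonation ignores terrain (elevation enters the forest as a plain
  feature instead).
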