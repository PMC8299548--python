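# Methods

## Change confidence from uncertainty intervals

Each observation `(v, u)` defines the interval `[v − u, v + u]` of
plausible true values, with `u` a one-sigma half-width in the variable's
own units (LAI dimensionless ≥ 0, FAPAR a fraction in [0, 1]). The
confidence of a consecutive change is

    C_f = 100 · (1 − O_l / f_l),

where `O_l` is the geometric intersection length of the two intervals,
clamped at zero when they are disjoint, and `f_l` the span of their
union envelope `[min lower, max upper]`. This geometric reading is the
one the overlap picture defines: the branch-form expressions for `O_l`
(one branch per sign of the change) coincide with the intersection
whenever neither interval contains the other, but can exceed it under
containment and can go negative for disjoint intervals; the
intersection/envelope form is used everywhere, and the test suite pins
it against an independent grid-sampling oracle.

Degenerate cases are fixed as: `Δv = 0 → C_f = 0` (the two classification
branches only cover strict increases and decreases), and `f_l = 0`
(identical values with zero uncertainties) `→ C_f = 0`, avoiding 0/0.
Consequences worth knowing: `C_f = 100` iff the intervals are disjoint;
`C_f` is symmetric in the two observations, invariant under common
rescaling of all values and uncertainties, and never increases when both
uncertainties widen.

A change is *increase*/*decrease* only when `C_f` strictly exceeds the
threshold (default 50 %; "above" is read as strict), with the sign of
`Δv` giving the direction; otherwise *non-significant* (NC). Missing or
QC-flagged observations are handled by pairwise deletion — a step enters
the analysis only when both variables are valid at both of its ends —
with no gap filling, mirroring how low-quality satellite retrievals are
excluded rather than imputed.

## Contingency table and metrics

Simultaneous class pairs are counted into a 3 × 3 table with rows = LAI,
columns = FAPAR and index 1 = decrease, 2 = NC, 3 = increase. The five
metrics (OA, Si, Sd, Bnc, Bns; formulas in the README) are carried as
fractions; the CLI and reports render percentages. Undefined metrics —
an empty table, or a Dice denominator of zero (no significant increase
mass anywhere for `Si`, mutatis mutandis `Sd`) — propagate as NaN, never
as 0, so downstream averages are not silently biased. `Bns` is oriented
so that a positive value means the LAI change is the non-significant one
more often than FAPAR's. The senescence asymmetry of real canopies
(FAPAR can drop while LAI holds) is deliberately not special-cased; such
events surface in the bias metrics, which is the point of having them.

## Temporal and spatial consistency

* **Temporal (map) approach** — one table per consecutive step over all
  pixels of a region/stratum → a metric time series.
  `processed_fraction` relates each step's case count to the stratum's
  pixel count. The series is indexed by the composite start date of the
  later composite of the step; months are keyed by that start date,
  which is stable across 8-, 10- and 16-day cadences.
* **Spatial (pixel) approach** — one table per pixel over the full
  record → metric maps.

The two are consistent by construction: summing per-step tables over
time equals tabulating all (pixel, step) cases at once (asserted as a
test invariant).

Monthly climatologies first average within each (year, month), then take
the mean and inter-annual standard deviation across years, so one year
of data reproduces itself with zero dispersion. Long-term trends use the
Seasonal Mann-Kendall test: the Kendall S statistic and its
tie-corrected variance are computed within each calendar-month season
and summed, significance from the continuity-corrected two-sided normal
approximation. No inter-season covariance (Hirsch–Slack) correction is
applied; for the ~36-observation seasons produced by multi-year dekadal
records the type-I error stays near the nominal level (checked by Monte
Carlo in the suite). The per-season statistic is cross-checked against
`scipy.stats.kendalltau`. Between-product differences on a stratum use
the Welch unequal-variance t test (means) and the two-sample
Kolmogorov–Smirnov test (distributions), pairwise between products, at
α = 0.05 throughout, without multiple-testing correction across strata —
each stratum is reported as its own test. Zonal means are
area-unweighted averages over half-open latitude bands `[edge, edge + Δ)`
anchored at integer multiples of the band width.

## Threshold sensitivity

`C_f` does not depend on the threshold, so sweeps compute it once and
re-classify cheaply. The joint sweep applies one threshold to both
variables (defaults 25/50/75 %); the independent sweep maps `Bns` on a
101 × 101 grid of 1 % steps, computed by sorted-confidence counting in a
single pass. Two monotonicities follow from the classification rule and
are asserted: `n22` never decreases and `n13 + n31` never increases with
the joint threshold. The zero-`Bns` locus collects grid cells where
`|Bns|` falls below one-count resolution (`1/(2N)`) or where the sign
flips between neighbours; the joint-threshold crossing is the first
genuine sign change along the diagonal (linearly interpolated), ignoring
trivially balanced cells at the sweep ends — at threshold 0 or 100
`Bns` vanishes for lack of NC or significant cases, which is not a
crossing. An all-one-sign surface yields an empty locus with a
diagnostic rather than a fabricated crossing.

## Spatial aggregation

Coarsening uses inverse-variance weights `w_i = 1/δ_i²`:
`Rs = Σ w_i α_i / Σ w_i` and `σ_s = 1/√(Σ w_i)` (the standard propagated
form consistent with the weighted mean). Source pixels must nest exactly
into target cells (membership by pixel centre, half-open cells anchored
at the grid origin); cells below a minimum valid-pixel fraction
(default 0.5, configurable) are invalidated. Zero uncertainties are
floored at ε = 10⁻⁶ native units with a logged count so weights stay
finite. With equal uncertainties the weighted mean reduces to the block
mean to float precision. Land cover is resampled by majority filter with
ties broken toward the smallest class code. The multiscale analysis
aggregates each ECV with its own uncertainties, majority-resamples the
class map, and re-runs the entire classification pipeline per resolution
and stratum.

## Synthetic paired products

The generator emulates the statistical structure the framework consumes,
not radiative-transfer physics:

* **Seasonality** — `LAI(t) = baseline + amplitude · max(0, sin(2π(doy −
  phase)/365))^sharpness`, per land-cover class (cropland, forest,
  shrub, grassland in quadrant blocks), plus a static ±5 % per-pixel
  heterogeneity. Defaults give desk-scale tiles (32 × 32 at 0.01°,
  dekadal compositing: days 1/11/21, 36 composites/year; 8- and 16-day
  cadences restart on 1 January as MODIS-style composites do).
* **Physical link** — `FAPAR = 1 − exp(−k·LAI)` with k = 0.5, the
  Beer–Lambert saturating absorption law, so true changes always share a
  sign.
* **Uncertainty archetypes** — `propagated` (large relative LAI
  uncertainty ~35 %, smaller FAPAR ~12 %: products whose FAPAR is
  derived through a radiative-transfer state after LAI), `retrieval`
  (small uncertainties, LAI ~5 %, FAPAR ~10 %: LUT-solution spreads) and
  `decoupled` (independent additive + relative models per variable:
  separately retrieved products). `uncertainty_scale` rescales the
  stated uncertainties; with both it and `noise_scale` at zero the
  scenario is exactly deterministic and every true change carries 100 %
  confidence — the perfect-agreement limit.
* **Pathologies** — non-coherence: each FAPAR increment's sign flips
  with probability `p`, and the series is rebuilt by cumulative
  summation so levels stay realistic; uncertainty drift: stated
  uncertainties are multiplied by `1 + β·(t − t_b)` after a break index
  `t_b` while the actual noise keeps following the base uncertainties —
  the drift models reported-uncertainty miscalibration (as across a
  sensor transition), and scaling noise along with it would cancel out
  of the scale-invariant confidence; `post_break_noise` separately
  scales the real noise after the break; QC dropout invalidates
  observations at random.
* Gaussian noise with sd equal to the stated uncertainty, truncated at
  physical bounds (LAI ≥ 0, FAPAR ∈ (0, 1)); truncation counts are kept
  in the truth record. The same seed reproduces bit-identical stacks.

What the generator does **not** emulate: spatially correlated retrieval
errors, cloud-pattern gaps, biome-dependent link curvature, snow/albedo
effects, or mixed pixels. Passing tests therefore demonstrate that the
framework recovers what it is designed to measure under its own
assumptions, not that any real product pair is consistent.

## Problem sizes and study conditions

Recovery and power checks run at deliberate desk scale: the
non-coherence recovery uses a 32 × 32 tile over one growing season
(May–August window where every true change is non-zero), giving
N > 10,000 pixel-steps against the 95 % binomial interval around
p = 0.1; trend detection uses 100 replicates of a 24 × 24, three-year
scenario with the FAPAR reported uncertainty doubling within ~1.4 years
(β = 0.02 per dekadal step), detected by the seasonal Mann-Kendall test
on the `Bns` series at α = 0.05; the end-to-end pipeline demonstration
runs a 32 × 32 × 3-year scenario through every stage including three
coarser resolutions.

## Known limitations

* NetCDF I/O uses the NETCDF3-classic format (scipy backend); TIFF maps
  carry grid geometry in a JSON sidecar rather than embedded geo-tags.
* The seasonal Mann-Kendall variance ignores inter-season covariance;
  for strongly autocorrelated metric series the test is anticonservative.
* Aggregation assumes exact grid nesting; no reprojection or geodesic
  area weighting.
* Metrics treat cases as independent; spatial autocorrelation within a
  region narrows the effective sample size and is not corrected for.
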