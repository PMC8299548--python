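# ecvagree

Uncertainty-aware consistency analysis for physically linked vegetation
essential climate variables (ECVs): leaf area index (LAI) and the
fraction of absorbed photosynthetically active radiation (FAPAR).

## The problem

LAI and FAPAR are coupled through the canopy's absorption of radiation:
when leaf area grows, absorbed PAR grows with it. A satellite product
pair that reports a significant LAI change without a matching FAPAR
change (or changes of opposite sign) is physically inconsistent — and
whether a change is *significant* depends entirely on the uncertainties
the product reports with each value. `ecvagree` turns this physical
constraint into a quantitative screening tool for product validation:
it classifies every consecutive temporal change of both variables using
their per-observation uncertainties and summarises how often, where and
when the two products tell the same story.

## The method

For consecutive observations `(v_t, u_t)` and `(v_{t+1}, u_{t+1})`,
where `u` is a one-sigma uncertainty half-width, the change confidence
is the non-overlap fraction of the two intervals `[v - u, v + u]`:

    C_f = 100 · (1 − O_l / f_l)

with `O_l` the intersection length of the intervals (0 when disjoint)
and `f_l` the span of their union envelope. A change is an *increase* or
*decrease* only when `C_f` strictly exceeds a threshold (50 % by
default); otherwise it is *non-significant* (NC). Simultaneous
LAI × FAPAR classes populate a 3 × 3 contingency table `n_ij`
(rows LAI, columns FAPAR; 1 = decrease, 2 = NC, 3 = increase), giving

* `OA  = (n11 + n22 + n33) / N` — overall agreement,
* `Si  = 2·n33 / (2·n33 + n32 + n31 + n23 + n13)` — increase sensitivity
  (Dice coefficient, growing season),
* `Sd  = 2·n11 / (2·n11 + n12 + n13 + n21 + n31)` — decrease sensitivity
  (senescence),
* `Bnc = (n13 − n31) / N` — non-coherent bias,
* `Bns = ((n21 + n23) − (n12 + n32)) / N` — non-significant bias.

On top of the per-table metrics the package provides: per-time-step
regional metric series (temporal consistency) with monthly climatologies
and the Seasonal Mann-Kendall trend test; per-pixel metric maps (spatial
consistency) with Welch and Kolmogorov–Smirnov two-sample comparisons
between products; joint and independent confidence-threshold sweeps with
the zero-`Bns` locus; inverse-variance weighted aggregation to coarser
grids (`Rs = Σ w_i α_i / Σ w_i`, `w_i = 1/δ_i²`, `σ_s = 1/√(Σ w_i)`)
with land-cover majority resampling; and a seeded synthetic paired-product
generator (seasonal LAI cycles per land-cover class, Beer–Lambert link
`FAPAR = 1 − exp(−k·LAI)`, product-style uncertainty archetypes, injected
non-coherence, uncertainty drifts and sensor breaks) so every stage is
testable with known ground truth.

## Worked example

```python
from ecvagree import Observation, confidence_level

rec = confidence_level(Observation(0.30, 0.06, 0), Observation(0.38, 0.06, 1))
print(rec.confidence)   # 80.0
```

The intervals `[0.24, 0.36]` and `[0.32, 0.44]` overlap by 0.04 over a
full range of 0.20, so the change is real with 80 % confidence — above
the 50 % threshold, hence classified as an increase.

`examples/` contains one short script per capability. For instance
`python examples/03_consistency_analysis.py` generates a three-year
scenario whose reported FAPAR uncertainty doubles within ~1.4 years and
prints:

```
temporal series: 107 steps, mean OA = 0.447, mean Bns = -0.304
seasonal Mann-Kendall on Bns: S = -321, p = 1.8e-22, trend sign = -1
Welch t = -8.55 (p = 3.9e-17), KS D = 0.300 (p = 2.5e-23)
```

The significant negative `Bns` trend recovers the injected uncertainty
drift — ever more FAPAR changes fall below the confidence threshold
while the LAI changes do not — and the two-sample tests distinguish the
drifted product's agreement map from an undrifted twin.

A thin CLI mirrors the pipeline stages
(`ecvagree simulate|classify|temporal|spatial|sweep|aggregate|report`);
`ecvagree report --config run.yaml` writes metric series, maps,
climatologies, trend tables, threshold surfaces and provenance for a
full run.

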