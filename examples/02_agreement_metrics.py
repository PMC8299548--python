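"""Agreement and bias metrics of simultaneous LAI/FAPAR change classes.

A season of paired observations is classified step by step; the nine
possible simultaneous class combinations populate a 3x3 contingency
table from which the five metrics follow.
"""

import numpy as np

from ecvagree import Observation, classify_series, compute_metrics, tabulate

# one growing season: LAI ramps up then down; FAPAR follows through a
# saturating light-absorption link, with modest uncertainties
lai_values = np.concatenate([np.linspace(0.5, 3.0, 10), np.linspace(3.0, 0.5, 8)])
fapar_values = 1 - np.exp(-0.5 * lai_values)
rng = np.random.default_rng(0)
lai = [Observation(v + rng.normal(0, 0.05), 0.15, t)
       for t, v in enumerate(lai_values)]
fapar = [Observation(f + rng.normal(0, 0.01), 0.02, t)
         for t, f in enumerate(fapar_values)]

pairs = classify_series(lai, fapar)
table = tabulate(pairs)
print("contingency table (rows LAI, cols FAPAR):")
print(table.to_frame())
metrics = compute_metrics(table)
print()
for name, value in metrics.as_dict(percent=True).items():
    if name in ("OA", "Si", "Sd", "Bnc", "Bns"):
        print(f"  {name:4s} = {value:+6.1f} %")
print(f"  N    = {metrics.n} simultaneous changes")
print()
print("OA is the coherent (diagonal) fraction; Si/Sd are Dice sensitivities "
      "of simultaneous increases/decreases; Bnc and Bns measure directional "
      "and significance imbalances between the two variables.")
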