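"""How the agreement metrics respond to the confidence-threshold choice.

Sweeps the joint threshold (same value for both variables) and the full
independent per-variable grid, then locates where the non-significant
bias Bns balances to zero.
"""

import numpy as np

from ecvagree import (ScenarioConfig, generate, sweep_independent, sweep_joint,
                      zero_bias_locus)

# propagated-link archetype: LAI carries the larger relative uncertainty
sc = ScenarioConfig(seed=7, ny=24, nx=24, n_years=2, archetype="propagated")
lai, fapar, *_ = generate(sc)

joint = sweep_joint(lai, fapar, [25.0, 50.0, 75.0])
print("joint sweep (threshold applied to both ECVs):")
print(joint[["OA", "Si", "Sd", "Bnc", "Bns", "n22", "noncoherent"]].round(3))

surface = sweep_independent(lai, fapar)  # 101 x 101 grid, 1% steps
locus = zero_bias_locus(surface)
print(f"\nBns surface: {surface.shape[0]}x{surface.shape[1]} thresholds, "
      f"{surface.attrs['n_cases']} cases")
print(f"zero-bias locus: {len(locus.points)} grid cells; "
      f"joint-threshold crossing at "
      f"{'none' if locus.diagonal_crossing is None else f'{locus.diagonal_crossing:.1f}%'}")
if locus.diagnostic:
    print("diagnostic:", locus.diagnostic)
print()
print("Matching non-significant changes (n22) grow with the threshold while "
      "non-coherent significant changes shrink; a positive mid-range Bns "
      "says FAPAR changes stay significant at thresholds where LAI's do not "
      "(smaller relative FAPAR uncertainties).")
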