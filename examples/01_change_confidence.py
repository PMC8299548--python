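"""Confidence level of a single consecutive change.

Two observations of the same variable, each with a one-sigma uncertainty,
define two intervals; the change confidence is the fraction of the
combined envelope NOT shared by both intervals.
"""

from ecvagree import ClassificationConfig, Observation, classify_change, confidence_level

pairs = {
    "disjoint intervals": (Observation(0.20, 0.05, 0), Observation(0.50, 0.05, 1)),
    "partial overlap": (Observation(0.30, 0.06, 0), Observation(0.38, 0.06, 1)),
    "heavy overlap": (Observation(0.30, 0.10, 0), Observation(0.34, 0.10, 1)),
    "no change": (Observation(0.30, 0.05, 0), Observation(0.30, 0.05, 1)),
}

config = ClassificationConfig(confidence_threshold=50.0)
for label, (prev, nxt) in pairs.items():
    rec = confidence_level(prev, nxt)
    cls = classify_change(rec, config)
    print(f"{label:20s} delta={rec.delta:+.2f}  Cf={rec.confidence:5.1f}%  -> {cls}")

print()
print("A change counts as increase/decrease only when its confidence "
      "strictly exceeds the 50% threshold; otherwise it is non-significant.")
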