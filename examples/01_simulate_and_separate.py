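"""Separate two synthetic brain states with a single predictive coefficient.

Generates a small two-condition dataset (4-channel sessions whose spectral
peak differs in location and width), runs the preprocessing chain, reduces
each 1-minute epoch to the order-1 feature (1 - a1) * 1e3, and fits the
midpoint decision threshold.
"""

import dataclasses

from lpcsep import (
    LEVODOPA_LIKE,
    SALINE_LIKE,
    analyze_separation,
    extract_features,
    gen_condition_pair,
)

# 5-minute sessions keep this example fast; the study-scale default is 40 min
spec_a = dataclasses.replace(SALINE_LIKE, duration_min=5.0)
spec_b = dataclasses.replace(LEVODOPA_LIKE, duration_min=5.0)
recordings = gen_condition_pair(n_subjects=2, spec_a=spec_a, spec_b=spec_b, seed=42)

table = extract_features(recordings, methods=("lpc1",), epoch_lengths_min=(1.0,))
saline = table.values_for("lpc1", "saline")
levodopa = table.values_for("lpc1", "levodopa")

res = analyze_separation(saline, levodopa, "saline", "levodopa")
print(f"saline feature:   {saline.mean():.3f} +/- {saline.std():.3f}  (n={len(saline)})")
print(f"levodopa feature: {levodopa.mean():.3f} +/- {levodopa.std():.3f}  (n={len(levodopa)})")
print(f"threshold {res.threshold:.3f}, margin {res.margin:.3f}, "
      f"complete separation: {res.complete_separation}")
print(f"rank-sum p = {res.wilcoxon_p:.3g}, Kruskal-Wallis p = {res.kruskal_p:.3g}")
print("-> the broader-bandwidth (levodopa-like) state has the larger feature;")
print("   a positive margin means every epoch classifies correctly by threshold.")
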