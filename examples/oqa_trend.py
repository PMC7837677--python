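"""Optical quantal analysis of a synthetic spine population.

Generates 67 spines x 20 paired-pulse trials with release probability rising
along the dendrite (P1 = 0.18 + 0.0012·x plus biological scatter), estimates
P1/P2/P2*/PPR per spine from the outcome counts, and regresses the estimates
against distance — raw and pooled into 25 µm bins.  Binning averages out the
per-synapse scatter and raises Pearson's r without changing the trend.
"""

import numpy as np

from synaptrend.quantal import bin_and_pool, count_outcomes, estimate_release, regress_trend
from synaptrend.synthetic import generate_spine_dataset

data = generate_spine_dataset(n_spines=67, trials_per_spine=20, seed=42)
x = np.array([spine.distance_soma for spine, _ in data])
ests = [estimate_release(count_outcomes(trials)) for _, trials in data]
p1 = np.array([e.P1 for e in ests])
ppr = [e.PPR for e in ests if e.PPR is not None]

print(f"n = {len(x)} spines, mean P1 = {p1.mean():.3f}, mean PPR = {np.mean(ppr):.2f}")

raw = regress_trend(x, p1)
print(f"P1 vs distance: slope = {raw.slope:.5f} per um "
      f"(truth 0.00120), r = {raw.pearson_r:.2f}, p = {raw.p_value:.1e}")

binned, pooled = bin_and_pool(x, p1, bin_width=25.0)
print(f"25-um binned:   slope = {pooled.slope:.5f} per um, "
      f"r = {pooled.pearson_r:.2f}  ({len(binned)} bins)")
print("-> the same dataset, but pooling removes symmetric scatter: "
      "r rises while the slope stays put.")
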