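# synaptrend

Analysis and simulation toolkit for the dendritic distribution of
neurotransmitter release probability (P_r) at CA3–CA1 synapses, and its
consequences for synaptic integration in CA1 pyramidal cells.

It is written for synaptic physiologists and modellers who work with
single-synapse optical quantal analysis (OQA), glutamate-sensor (iGluSnFR)
imaging, or compartmental models of pyramidal cells, and want the complete
chain — trial scoring, release-probability estimation, distance-trend
statistics, and stochastic-synapse simulation — as tested, importable code.

## What it computes

**Optical quantal analysis.** Paired-pulse Ca²⁺ imaging trials at single
dendritic spines are scored success/failure against a 2-SD failure-noise
criterion; with nAB the outcome counts over N trials,

    P1  = (n10 + n11) / N            first-pulse release probability (= P_r)
    P2  = (n01 + n11) / N            second-pulse release probability
    P2* = n01 / (n00 + n01)          conditioned on first-pulse failure
    PPR = P2 / P1,   PPR* = P2* / P1

Distance trends (P1, PPR, spine density, within-branch pairwise
differences, relative branch position) are OLS regressions with slope
t-tests and Pearson's r, plus 25 µm distance binning that pools out
per-synapse scatter.

**Glutamate-sensor signals.** ΔF/F0 normalisation, tail-corrected
paired-pulse amplitude ratios, and the five-pulse burst fit
ΔF/F0(t) = Σᵢ Aᵢ·exp(−(t − 50·(i−1))/τ), which reconstructs 20 Hz release
kinetics from slow frame-mode scans; the slope of Aᵢ vs i indexes
short-term plasticity during the burst.

**Dendritic integration.** A branched compartmental cable solver
(Crank–Nicolson over the tree, Exp2Syn-convention synapses, minimal
Hodgkin–Huxley soma) hosts 50 stochastic synapses whose release
probability is either uniform (P1 = 0.36, P2 = 0.77) or follows the
measured trends P1(x) = 0.18 + 0.0012·x and
P2(x) = P1(x)·(3.31 − 0.0074·x), with synaptic conductance scaling
Gm(x) = A·(0.51 + 0.002·x). Paired-pulse, five-pulse burst and
Poisson-drive protocols compare the conditions at matched random seeds.

**Synthetic data.** Every input the analyses assume can be generated with
known ground truth: spine trial tables with the distance trend and
biological scatter, noisy linescan traces, spillover-mixed iGluSnFR traces
(~67 neighbouring synapses per 2 µm detection sphere), and SWC morphologies.

## Worked example

```
$ python examples/oqa_trend.py
n = 67 spines, mean P1 = 0.421, mean PPR = 2.16
P1 vs distance: slope = 0.00155 per um (truth 0.00120), r = 0.73, p = 2.7e-12
25-um binned:   slope = 0.00141 per um, r = 0.91  (13 bins)
```

Sixty-seven simulated spines (20 paired-pulse trials each) recover the
built-in release-probability gradient: the fitted slope's confidence
interval covers the true 0.0012 per µm, and pooling the same estimates into
25 µm bins raises Pearson's r from 0.73 to 0.91 without moving the slope —
binning removes symmetric per-synapse scatter, not information about the
trend.

```
$ python examples/paired_pulse_conditions.py
  uniform: EPSP1 = 7.91 +/- 0.21 mV, PPR = 1.44 +/- 0.06  (n = 30)
 pr_trend: EPSP1 = 9.04 +/- 0.20 mV, PPR = 1.10 +/- 0.04  (n = 30)
```

With identical placement and release seeds, giving the 50 synapses the
distance-dependent P_r field instead of a uniform one raises the compound
first EPSP by ~14% and lowers the compound paired-pulse ratio by ~23% —
the signature of a centrifugal release-probability gradient working with
centrifugal receptor scaling.

Other examples: `linescan_classification.py` (trial scoring round-trip),
`iglu_ppr_burst.py` (spillover-mixed PPR and frame-mode burst fits),
`cable_epsp.py` (somatic EPSP vs synapse distance).

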