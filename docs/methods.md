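# Methods

`synaptrend` studies how neurotransmitter release probability (P_r) is
distributed along the apical dendrites of CA1 pyramidal cells and what that
distribution does to synaptic integration. It has three layers: estimators
for optical quantal analysis (OQA) and glutamate-sensor imaging; generators
that synthesise the imaging data those estimators assume; and a
stochastic-synapse compartmental model that compares uniform against
distance-dependent release-probability fields on a branched neuron.

## Quantal estimators

Each paired-pulse trial at one dendritic spine is scored success/failure per
pulse. With nAB the count of trials with first-pulse flag A and second-pulse
flag B out of N trials:

    P1  = (n10 + n11) / N
    P2  = (n01 + n11) / N
    P2* = n01 / (n00 + n01)
    PPR = P2 / P1,  PPR* = P2* / P1

P2* uses only first-pulse failures, sidestepping indicator saturation when a
second success rides a first. Undefined cases (P1 = 0, or no first-pulse
failures) are returned as `None`, never silently coerced; experimentally
such synapses were excluded, and the exclusion should stay visible.

**Trace classification.** A pulse is a success iff its response amplitude
exceeds k·SD (k = 2) of the failure-signal noise. The amplitude measure is
the peak of the 10 ms boxcar-smoothed trace within a 5–45 ms post-stimulus
window; smoothing keeps the raw-noise maximum over the window well below
the criterion while barely attenuating the ~100 ms Ca²⁺ transient. Because
a second response rides the decay of the first, later pulses are scored
against the mean signal level in the 20 ms before their stimulus rather
than the pre-trial baseline. Ensemble classification
(`classify_trials`) makes one deterministic refinement pass: after a first
pass against per-trace baseline SD, the per-sample SD of the signal during
first-pulse failures is pooled and every trace is re-scored against it.
On 6–8 SD synthetic data this recovers ground-truth outcomes essentially
perfectly; at lower signal-to-noise the 2-SD criterion degrades gracefully
(false positives before false negatives).

**Trend statistics.** Distance trends are ordinary least squares with the
two-sided slope t-test and Pearson's r, reported per test without
multiple-testing correction. `bin_and_pool` averages x and y within 25 µm
distance bins and re-runs the regression on bin means: symmetric
per-synapse scatter cancels, so r rises while the slope estimate is
preserved — the point being that trend significance, not per-synapse
predictive power, is the quantity of interest. Percentage P_r differences
between same-branch pairs use the pair mean as the (symmetric) reference.
Paired condition comparisons offer both the paired t-test and the Wilcoxon
signed-rank test; selection is a caller decision.

## Glutamate-sensor analysis

ΔF/F0 = (F − F0)/F0 with F0 averaged over ~150 ms before the first
stimulus. For paired pulses, A1 is the ΔF/F0 peak after pulse 1; the raw
second peak is corrected by subtracting the mono-exponential tail of
response 1 fitted between the pulses; PPR = A2/A1, oriented so facilitation
gives PPR > 1. Five-pulse (20 Hz) bursts are fitted with five overlapping
mono-exponential transients sharing one decay constant τ:

    ΔF/F0(t) = Σᵢ Aᵢ exp(−(t − Δt·(i−1))/τ),   Δt = 50 ms.

After the fifth pulse every component decays with the same τ, so the tail
is a single exponential fitted first (nonlinear least squares); with τ
fixed the amplitudes follow by linear least squares, which is what lets
20 ms frame-mode scans recover kinetics far faster than the frame interval.
The burst's facilitation index is the OLS slope of the fitted Aᵢ against
the stimulus index; on noiseless bursts amplitudes and τ are recovered to
well under 1% (under 5% from 20 ms frames).

## Synthetic data: what it emulates and what it does not

**Spine trial tables.** Spines are uniform on 40–350 µm path distance.
True P1(x) = 0.18 + 0.0012·x plus Gaussian biological scatter
(SD 0.12 — release fidelity at one distance spans roughly 0.05–0.7, and
without this scatter the unbinned correlation would be unrealistically
high); true P2 = P1·PPR(x) with PPR(x) = 3.31 − 0.0074·x; probabilities
clipped to [0.01, 0.99] (exact 0/1 requests stay degenerate). Second-pulse
outcomes are drawn independently of the first: only the marginal P2 and the
conditional P2* are observable, and independence makes E[P2*] = E[P2] by
construction, matching their empirical similarity; a correlation hook
exists for sensitivity checks. Trials default to 20 per spine (observed
range 14–30).

**Linescan traces.** 500 Hz sampling; successes add a dual-exponential
transient (3 ms rise, 100 ms decay) with lognormal amplitude
(mean 6 SD of baseline noise, CV 0.3 — the real amplitude distribution is
uncharacterised and this knob claims no fidelity); Gaussian baseline noise
throughout. Not modelled: indicator saturation and buffering,
photobleaching, focal drift, the microscope point-spread function. Passing
round-trip tests therefore shows the estimators are correct for
well-separated success/failure amplitudes, not that they would survive
every pathology of real recordings.

**Spillover-mixed glutamate traces.** Released glutamate travels ~2 µm;
at ~2.0 synapses per µm³ that sphere (~33.5 µm³) holds 67 neighbours, so an
extracellularly evoked sensor signal pools many synapses and failures
become undetectable ((1 − 0.36)⁶⁷ ≈ 10⁻¹³). Each trace sums per-neighbour
Bernoulli releases convolved with a mono-exponential sensor kernel
(τ = 40 ms, chosen to match the shape of published transients). The
printed density "~2.0 µm⁻²" is read as volumetric (µm⁻³): only then does
density × sphere volume reproduce the stated >60 neighbours. Per-bouton
ground-truth PPR falls linearly with distance from the cell-body layer
(defaults average to ≈1.49); burst mode applies a per-pulse facilitation
slope rising with distance (s(x) = −0.05 + 0.0006·x).

**Synthetic morphology.** A soma (10 µm radius) with a tapering apical
trunk (5.0 → 2.5 µm diameter over 400 µm), 39 short oblique branches
(1.0 µm diameter, 50 µm) covering every path distance in 40–350 µm, and 14
basal dendrites (3.0 µm, 400 µm) providing the load of the missing rest of
the cell. Schaffer-type synapses are placed on the obliques, as in the
tissue. Dendritic spine membrane is folded into the cable as a 3× area
multiplier on dendritic compartments. These choices put the *uniform*
condition of the integration experiments in the reference operating regime
— compound EPSP of a few millivolts, clearly sublinear summation, no
spiking at the subthreshold conductance scale — on a cell a fraction of the
size of a reconstructed neuron. Absolute millivolt values are therefore
not comparable to recordings; condition *contrasts* are the meaningful
output.

## Cable model

Frustum compartments ≤ 10 µm (taper interpolated within unbranched
same-calibre chains; a thin branch leaving a thick trunk keeps its own
calibre from its first segment). Passive parameters: Ra = 90 Ω·cm,
Cm = 1 µF/cm² (the source value printed as "1 mF/cm²" is read as a unit
typo; 1 mF/cm² is three orders of magnitude off any biological membrane),
Rm = 28 kΩ·cm², rest −65 mV. Integration is Crank–Nicolson with Hines
elimination over the tree (exact O(n) solve per step), fixed
dt = 0.025 ms; the variable-step integration of the reference simulator is
replaced by this fixed step, justified by convergence tests (halving dt
moves EPSP peaks by < 0.5%; steady-state attenuation on a 5.3 mm uniform
cylinder matches exp(−x/λ), λ = √(r·Rm/2Ra) ≈ 882 µm, to better than
0.1%). Synapses are dual-exponential conductances (1 ms rise, 20 ms decay,
E_rev = 0) normalised so the peak equals Gm, the convention of the
reference simulator's Exp2Syn object; the raw difference-of-exponentials
form is available behind a flag.

Active currents are a minimal Hodgkin–Huxley Na/K pair. The soma
compartment lumps the axon initial segment, so its default densities
(gNa = 3.0, gK = 0.8 S/cm²) are initial-segment-scale, tuned once so the
cell fires with a monotone rate response under strong (A = 0.06 µS)
synaptic drive. Optional dendritic densities exist for thin apical
branches and the trunk but default to zero: with these first-order
kinetics, graded subthreshold boosting proved unachievable (K suppresses
distal inputs; Na alone destabilises rest or produces all-or-none
dendritic spikes). Channel kinetics are not temperature-scaled; the
temperature field is bookkeeping.

**EPSP measurement.** Pulse-1 amplitude is the somatic peak minus the
pre-protocol rest. Pulse-2 defaults to peak minus the voltage at its own
onset; both this and the absolute-baseline variant are recorded. The onset
convention systematically under-reads the second amplitude by roughly 30%
(the first response keeps decaying over the second peak's latency — a
measurement bias, verified against exact superposition of single-event
traces, not a physical depression). Spike detection is upward threshold
crossing (default 0 mV) with a 2 ms refractory merge.

## Stochastic synapses and short-term plasticity

Fifty synapses per run, positions i.i.d. in path distance on 40–350 µm —
uniform, or with a linear density rising ~2× across the range (the
measured spine-density trend; its printed regression coefficients are not
available, so the doubling is this package's calibration). Release fields:
uniform (P1 = 0.36, P2 = 0.77) or the distance trend
P1(x) = 0.18 + 0.0012·x, P2(x) = P1(x)·(3.31 − 0.0074·x). Peak conductance
Gm(x) = A·(0.51 + 0.002·x), A = 0.002 µS subthreshold / 0.06 µS spiking.
Placement is regenerated every run; compared conditions share every seed
(placement, release), so contrasts are paired by construction.

**The 0.36-vs-0.414 discrepancy.** Averaged over uniform placement the
literal P1 trend gives a population mean of ≈0.414, not the 0.36 the
uniform condition uses, yet the source describes the trend condition as
mean-matched at 0.36. The two cannot both hold. The package defaults to
the literal formulas, because they quantitatively explain the reported
integration effects: the first-EPSP boost of the trend condition is then
≈ 0.414/0.36 ≈ +15% before cable effects (reported: ~13%), and the
population PPR falls from 2.14 to ≈1.70, i.e. ≈ −21% (reported: ~20%). A
`rescale_mean` switch multiplies P1 and P2 by a common factor so the
realised population mean is exactly 0.36 (the common factor preserves the
PPR(x) regression); in that strictly mean-matched comparison only the
covariance between P1(x) and synaptic efficacy remains, which on any
passive cell is bounded by a·b/3 ≈ 5% (a ≈ 0.45 the relative P1 spread,
b ≤ 0.34 set by the Gm ratio 2.05) — far below the reported boost. Both
modes are exposed and tested.

**STP engine.** For spike trains, per-spike release probability is
p_k = base_P·F_k·R_k, where the facilitation factor F relaxes to 1 with
τ_f (35 ms) and jumps by a fixed increment after each spike, and the
resource R recovers to 1 with τ_r (50 ms) after being depleted by the
utilisation U·F (U = 0.36). An isolated spike gives exactly base_P. The
classical jump-type utilisation update bounds the 50 ms paired-pulse ratio
below 2, while proximal synapses here reach PPR ≈ 3; the multiplicative F
state removes that ceiling. Consistency mode calibrates the increment per
synapse in closed form so the engine's 50 ms paired-pulse prediction equals
the synapse's P2/P1 field. Defaults converge to a frequency-dependent
steady state within ~4 spikes of a constant train, per the reported
phenomenology; the exact experimental STP parameters are not published in
the source text, so the engine claims the phenomenology, not the data.

**Protocols.** Paired pulse: 100 runs, synchronous stimuli 50 ms apart at
A = 0.002 µS; runs that spike are flagged and excluded. Five-pulse burst
(20 Hz): per-pulse release follows the measured burst facilitation-slope
profile by default (the uniform condition carries the same mean slope
without distance dependence); the calibrated STP engine is the
alternative model — calibrated only to the 50 ms PPR field it predicts
distally *decreasing* facilitation and suppresses the burst contrast.
Voltage transfer is the time integral of somatic depolarisation from the
first stimulus to 50 ms after the last (a peak measure is also recorded).
Poisson drive: independent trains per synapse, A = 0.06 µS, default 2 s
per run (1 s in the shipped acceptance runs), output rate from somatic
spike counts.

## Known limitations

* At the spiking conductance scale every release saturates its local
  branch, so the centrifugal Gm compensation cannot act there and per-event
  somatic efficacy falls ~30% from proximal to distal. Spiking on this
  cell is fluctuation-driven, and the uniform condition's larger proximal
  events win: the trend condition's input–output advantage comes out
  negative, unlike the reference model with its full dendritic channel
  complement (explicitly out of scope here). The acceptance suite reports
  this check honestly rather than tuning around it.
* The burst-transfer contrast depends on the facilitation-slope profile,
  whose distance coefficients are calibrated to direction and rough
  magnitude only.
* Single-compartment synapses (no spine neck resistance), one global
  synaptic kinetics per simulation, no NMDA voltage dependence, no
  vesicle-pool depletion, no release latency jitter.

## Problem sizes

Unit tests run in a few seconds. The acceptance suite uses 200 replicate
datasets of 67 spines × 20 trials for estimator recovery; 100 paired-pulse
runs per condition; 8 Poisson runs × 4 rates × 2 conditions at 1 s each;
and a 530-compartment cylinder for the cable oracle — about three minutes
in total. `scripts/acceptance.py` re-runs the same computations from
scratch with the caller's seed.
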