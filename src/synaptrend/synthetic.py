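"""Synthetic inputs for every analysis stage: spine trial tables with a
ground-truth distance trend, noisy Ca2+ linescan traces, spillover-mixed
glutamate-sensor traces, and branched test morphologies.

The generators encode the study conditions the analyses assume: release
probability rising linearly with synapse-soma distance
(P1(x) = 0.18 + 0.0012·x), the paired-pulse ratio falling
(PPR(x) = 3.31 − 0.0074·x), 14-30 paired-pulse trials per spine sampled at
500 Hz, and a glutamatergic synapse density of 2 µm⁻³ which makes any
extracellularly evoked glutamate signal a mixture of >60 neighbouring
synapses within a 2 µm detection radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphology import APICAL, SOMA, Morphology
from .traces import FluorescenceTrace
from .quantal import TrialOutcome

__all__ = [
    "GroundTruthSpine",
    "NoiseModel",
    "SpilloverConfig",
    "sphere_volume",
    "generate_spine_dataset",
    "generate_linescan_trace",
    "generate_linescan_trials",
    "generate_iglu_dataset",
    "generate_morphology",
    "spine_dataset_to_frame",
    "ground_truth_to_json",
]

P1_SLOPE_DEFAULT = 0.0012       # per µm, Pr regression
P1_INTERCEPT_DEFAULT = 0.18
PPR_SLOPE_DEFAULT = -0.0074     # per µm, PPR regression
PPR_INTERCEPT_DEFAULT = 3.31
LINESCAN_RATE_HZ = 500.0        # Ca2+ linescan sampling rate
FRAME_INTERVAL_MS = 20.0        # time-lapse frame mode
# five-pulse burst facilitation-slope profile vs distance (per-pulse fractional
# amplitude step s(x) = intercept + slope*x): slope statistic rises with
# distance from the pyramidal-cell layer
BURST_SLOPE_PROFILE = (0.0006, -0.05)


@dataclass(frozen=True)
class GroundTruthSpine:
    """Ground truth for one simulated dendritic spine."""

    spine_id: str
    distance_soma: float            # µm
    distance_branch_origin: float   # µm
    branch_length: float            # µm
    true_P1: float
    true_P2: float
    local_spine_density: int        # count per 10 µm

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_P1 <= 1.0 and 0.0 <= self.true_P2 <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.distance_branch_origin > self.branch_length:
            raise ValueError("branch coordinate exceeds branch length")


@dataclass(frozen=True)
class NoiseModel:
    """Amplitude and noise parameters for synthetic linescan traces.

    ``success_amplitude_mean`` / ``baseline_sd`` defaults to 6, keeping the
    2-SD success criterion comfortably meaningful.  Successful-transient
    amplitudes are drawn lognormally with coefficient of variation
    ``success_amplitude_cv`` (the true amplitude distribution at these
    synapses is not characterised; the knob makes no fidelity claim).
    """

    baseline_sd: float = 1.0
    success_amplitude_mean: float = 6.0
    success_amplitude_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be non-negative")
        if self.success_amplitude_mean <= 0:
            raise ValueError("success amplitude must be positive")


@dataclass(frozen=True)
class SpilloverConfig:
    """Local synapse neighbourhood reported by a glutamate-sensor pixel.

    The printed areal-looking density ~2.0 µm⁻² is treated as a volumetric
    2.0 µm⁻³: only then does density × sphere volume at the 2 µm glutamate
    travel radius reproduce the stated >60 neighbours in ~33 µm³.
    """

    synapse_density: float = 2.0    # µm⁻³
    detection_radius: float = 2.0   # µm
    activated_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.activated_fraction <= 1:
            raise ValueError("activated_fraction must be in (0, 1]")
        if self.synapse_density < 0 or self.detection_radius <= 0:
            raise ValueError("non-physical spillover geometry")

    @property
    def sphere_volume_um3(self) -> float:
        return sphere_volume(self.detection_radius)

    @property
    def n_neighbours(self) -> int:
        return int(math.floor(self.synapse_density * self.sphere_volume_um3))


def sphere_volume(radius_um: float) -> float:
    """Volume (µm³) of the glutamate detection sphere."""
    return 4.0 / 3.0 * math.pi * radius_um ** 3


# ---------------------------------------------------------------------------
# Spine paired-pulse trial datasets
# ---------------------------------------------------------------------------

def _clip_prob(p: np.ndarray | float) -> np.ndarray | float:
    """Clip probabilities into [0.01, 0.99]; exact degenerate requests
    (p <= 0 or p >= 1) stay exactly 0 or 1."""
    p = np.asarray(p, dtype=float)
    out = np.clip(p, 0.01, 0.99)
    out = np.where(p >= 1.0, 1.0, out)
    out = np.where(p <= 0.0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def generate_spine_dataset(
        n_spines: int = 67,
        trials_per_spine: int = 20,
        trend_slope: float = P1_SLOPE_DEFAULT,
        trend_intercept: float = P1_INTERCEPT_DEFAULT,
        distance_range: tuple[float, float] = (40.0, 350.0),
        ppr_trend: tuple[float, float] = (PPR_SLOPE_DEFAULT, PPR_INTERCEPT_DEFAULT),
        seed: int = 0,
        pulse_correlation: float = 0.0,
        pr_jitter_sd: float = 0.12,
) -> list[tuple[GroundTruthSpine, list[TrialOutcome]]]:
    """Simulate per-spine paired-pulse success/failure trial series.

    Spines are placed uniformly over ``distance_range``; true P1 follows the
    linear distance trend plus Gaussian biological scatter of SD
    ``pr_jitter_sd`` (release fidelity varies widely between synapses at any
    one distance — observed values span ~0.05-0.7 around the trend), and
    true P2 = P1 · PPR(x); both are clipped to [0.01, 0.99].  Second-pulse
    outcomes are drawn independently of the first
    by default (only the marginal P2 and the conditional P2* are reported
    experimentally, and independence makes the two estimators agree by
    construction); ``pulse_correlation`` introduces within-trial correlation
    through the conditional split when non-zero.
    """
    if n_spines <= 0 or trials_per_spine <= 0:
        raise ValueError("counts must be positive")
    lo, hi = distance_range
    if not (0 < lo < hi <= 400):
        raise ValueError("distance_range must be a non-empty interval within (0, 400] µm")
    rng = np.random.default_rng(seed)
    ppr_slope, ppr_intercept = ppr_trend
    out = []
    for i in range(n_spines):
        x = float(rng.uniform(lo, hi))
        jitter = rng.normal(0.0, pr_jitter_sd) if pr_jitter_sd > 0 else 0.0
        p1 = float(_clip_prob(trend_intercept + trend_slope * x + jitter))
        ppr = ppr_intercept + ppr_slope * x
        p2 = float(_clip_prob(p1 * ppr))
        branch_length = float(rng.uniform(60.0, 150.0))
        branch_pos = float(rng.uniform(0.0, branch_length))
        density = int(np.clip(np.round(rng.normal(3.5 + 0.012 * x, 1.2)), 1, None))
        spine = GroundTruthSpine(
            spine_id=f"spine{i:03d}", distance_soma=x,
            distance_branch_origin=branch_pos, branch_length=branch_length,
            true_P1=p1, true_P2=p2, local_spine_density=density)
        s1 = rng.random(trials_per_spine) < p1
        if pulse_correlation == 0.0:
            s2 = rng.random(trials_per_spine) < p2
        else:
            cov = pulse_correlation * math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
            p2_given1 = float(np.clip(p2 + cov / max(p1, 1e-12), 0, 1))
            p2_given0 = float(np.clip(p2 - cov / max(1 - p1, 1e-12), 0, 1))
            u = rng.random(trials_per_spine)
            s2 = np.where(s1, u < p2_given1, u < p2_given0)
        trials = [(int(a), int(b)) for a, b in zip(s1, s2)]
        out.append((spine, trials))
    return out


def ground_truth_to_json(dataset, path) -> None:
    """JSON sidecar of per-spine ground truth for a generated dataset."""
    import dataclasses
    import json
    with open(path, "w") as fh:
        json.dump([dataclasses.asdict(spine) for spine, _ in dataset], fh,
                  indent=2)


def spine_dataset_to_frame(dataset) -> pd.DataFrame:
    """Flatten a spine dataset to the per-trial CSV schema."""
    rows = []
    for spine, trials in dataset:
        for k, (s1, s2) in enumerate(trials):
            rows.append({"spine_id": spine.spine_id,
                         "distance_um": spine.distance_soma,
                         "branch_origin_um": spine.distance_branch_origin,
                         "branch_length_um": spine.branch_length,
                         "trial_idx": k, "s1": s1, "s2": s2})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ca2+ linescan traces
# ---------------------------------------------------------------------------

def _dual_exp(t: np.ndarray, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Unit-peak dual-exponential transient, zero before t = 0."""
    if not 0 < rise_ms < decay_ms:
        raise ValueError("need 0 < rise < decay")
    tp = rise_ms * decay_ms / (decay_ms - rise_ms) * math.log(decay_ms / rise_ms)
    norm = math.exp(-tp / decay_ms) - math.exp(-tp / rise_ms)
    g = (np.exp(-t / decay_ms) - np.exp(-t / rise_ms)) / norm
    g[t < 0] = 0.0
    return g


def generate_linescan_trace(
        outcome: TrialOutcome,
        noise: NoiseModel,
        stim_times: tuple[float, float] = (100.0, 150.0),
        kinetics: tuple[float, float] = (3.0, 100.0),
        duration_ms: float = 500.0,
        sample_rate_hz: float = LINESCAN_RATE_HZ,
) -> FluorescenceTrace:
    """Synthesise one ΔG/R-style paired-pulse linescan profile.

    Each successful pulse contributes a dual-exponential transient whose
    amplitude is drawn from the lognormal success distribution; Gaussian
    baseline noise is added throughout.  The ground-truth outcome travels in
    ``meta`` for round-trip tests against the trial classifier.
    """
    if max(stim_times) >= duration_ms:
        raise ValueError("stimulus outside the trace window")
    rng = np.random.default_rng(noise.seed)
    dt = 1000.0 / sample_rate_hz
    t = np.arange(0.0, duration_ms, dt)
    v = rng.normal(0.0, noise.baseline_sd, size=t.shape) if noise.baseline_sd > 0 \
        else np.zeros_like(t)
    amps = []
    for flag, s in zip(outcome, stim_times):
        if not flag:
            amps.append(0.0)
            continue
        cv = noise.success_amplitude_cv
        if cv > 0:
            sig2 = math.log(1 + cv * cv)
            amp = float(rng.lognormal(math.log(noise.success_amplitude_mean) - sig2 / 2,
                                      math.sqrt(sig2)))
        else:
            amp = noise.success_amplitude_mean
        amps.append(amp)
        v += amp * _dual_exp(t - s, *kinetics)
    return FluorescenceTrace(time_ms=t, values=v, stim_times=stim_times,
                             meta={"outcome": tuple(int(f) for f in outcome),
                                   "amplitudes": tuple(amps)})


def generate_linescan_trials(outcomes, noise: NoiseModel, **kwargs) -> list[FluorescenceTrace]:
    """One trace per outcome, with per-trial seeds derived from the model seed."""
    traces = []
    for k, outcome in enumerate(outcomes):
        nm = NoiseModel(baseline_sd=noise.baseline_sd,
                        success_amplitude_mean=noise.success_amplitude_mean,
                        success_amplitude_cv=noise.success_amplitude_cv,
                        seed=noise.seed + 7919 * (k + 1))
        traces.append(generate_linescan_trace(outcome, nm, **kwargs))
    return traces


# ---------------------------------------------------------------------------
# iGluSnFR traces with spillover mixing
# ---------------------------------------------------------------------------

def generate_iglu_dataset(
        n_boutons: int = 33,
        distance_range: tuple[float, float] = (25.0, 300.0),
        ppr_profile: tuple[float, float] = (-0.002, 1.81),
        spill: SpilloverConfig | None = None,
        mode: str = "paired",
        seed: int = 0,
        base_p1: float = 0.36,
        mean_amplitude: float = 0.37,
        noise_sd: float = 0.02,
        sensor_tau_ms: float = 40.0,
        trials_per_bouton: int = 1,
        burst_slope_profile: tuple[float, float] = BURST_SLOPE_PROFILE,
        frame_interval_ms: float = FRAME_INTERVAL_MS,
        f0: float = 100.0,
) -> list[FluorescenceTrace]:
    """Synthesise glutamate-sensor ΔF/F0 responses with spillover mixing.

    Each "bouton" trace sums stochastic releases from ``spill.n_neighbours``
    local synapses (every release adds one quantal mono-exponential sensor
    transient, decay ``sensor_tau_ms``), so single-synapse failures become
    invisible as the neighbourhood grows.  Per-bouton ground-truth PPR
    follows ``ppr_profile`` against distance from the pyramidal-cell layer;
    the default profile averages to the observed mean paired-pulse ratio of
    about 1.49.  Modes: ``paired`` (2 stimuli, 50 ms apart), ``burst5``
    (5 stimuli at 20 Hz), ``frame_subsampled`` (burst5 decimated to
    time-lapse frames).  Raw fluorescence is returned (F = F0·(1 + ΔF/F0))
    so the ΔF/F0 computation itself can be exercised downstream.
    """
    if mode not in ("paired", "burst5", "frame_subsampled"):
        raise ValueError(f"unknown mode {mode!r}")
    spill = spill if spill is not None else SpilloverConfig()
    n_eff = max(0, int(round(spill.n_neighbours * spill.activated_fraction)))
    if n_eff == 0:
        raise ValueError("spillover mode requires at least one neighbouring synapse")
    rng = np.random.default_rng(seed)
    lo, hi = distance_range
    n_pulses = 2 if mode == "paired" else 5
    dt_stim = 50.0
    stim0 = 200.0
    stim_times = tuple(stim0 + dt_stim * i for i in range(n_pulses))
    duration = stim_times[-1] + 250.0
    dt = 1000.0 / LINESCAN_RATE_HZ
    t = np.arange(0.0, duration, dt)
    slope_a, slope_b = burst_slope_profile
    traces = []
    for i in range(n_boutons):
        x = float(rng.uniform(lo, hi))
        ppr = ppr_profile[1] + ppr_profile[0] * x
        p1 = base_p1
        if mode == "paired":
            probs = [p1, float(_clip_prob(p1 * ppr))]
        else:
            s = slope_b + slope_a * x   # fractional amplitude step per pulse
            probs = [float(_clip_prob(p1 * (1 + s * k))) for k in range(n_pulses)]
        q = mean_amplitude / (n_eff * p1)   # quantal ΔF/F0 per release
        dff = np.zeros_like(t)
        expected = []
        for s_time, p in zip(stim_times, probs):
            # trial-averaged release count (boutons are recorded over many
            # trials and analysed on the average trace)
            n_rel = rng.binomial(n_eff * trials_per_bouton, p) / trials_per_bouton
            expected.append(n_eff * p * q)
            if n_rel:
                kern = np.where(t >= s_time, np.exp(-(t - s_time) / sensor_tau_ms), 0.0)
                dff += n_rel * q * kern
        if noise_sd > 0:
            dff = dff + rng.normal(0.0, noise_sd, size=t.shape)
        tt, ff = t, f0 * (1.0 + dff)
        if mode == "frame_subsampled":
            step = max(1, int(round(frame_interval_ms / dt)))
            off = step // 2   # frames deliberately not aligned with stimulus onsets
            tt, ff = t[off::step], ff[off::step]
        traces.append(FluorescenceTrace(
            time_ms=tt, values=ff, stim_times=stim_times,
            meta={"bouton_id": f"bouton{i:03d}", "distance_um": x,
                  "true_ppr": ppr, "pulse_probs": tuple(probs),
                  "expected_amplitudes": tuple(expected),
                  "sensor_tau_ms": sensor_tau_ms, "f0": f0,
                  "n_neighbours": n_eff}))
    return traces


# ---------------------------------------------------------------------------
# Synthetic branched morphology
# ---------------------------------------------------------------------------

def generate_morphology(
        trunk_length: float = 400.0,
        n_obliques: int = 39,
        oblique_spacing: float = 8.0,
        diameters: dict | None = None,
        seed: int | None = None,
        oblique_length: float = 50.0,
        first_oblique_um: float = 40.0,
        node_spacing: float = 10.0,
        soma_radius: float = 10.0,
        n_basal: int = 14,
        basal_length: float = 400.0,
) -> Morphology:
    """Build a soma + tapering apical trunk + oblique-branch test cell.

    Stands in for a reconstructed CA1 pyramidal neuron: a single apical
    trunk (diameter tapering trunk_base → trunk_tip) carrying thin oblique
    side branches — the branches that actually host Schaffer-collateral
    synapses — plus a basal dendritic tree that loads the soma the way the
    real cell's basal field does.  Obliques cover every path distance in the
    40-350 µm placement range; path distance is measured from the soma root
    node.
    """
    if trunk_length < 350.0:
        raise ValueError("trunk must reach at least 350 µm")
    d = {"trunk_base": 5.0, "trunk_tip": 2.5, "oblique": 1.0, "basal": 3.0}
    if diameters:
        d.update(diameters)
    if min(d.values()) <= 0:
        raise ValueError("diameters must be positive")
    rng = np.random.default_rng(seed)

    xyz = [[0.0, 0.0, 0.0]]
    radius = [soma_radius]
    parent = [-1]
    ntype = [SOMA]

    # basal dendrites: capacitive/conductive load, no synapse placement
    from .morphology import BASAL
    for j in range(n_basal):
        ang = 2 * math.pi * j / max(n_basal, 1)
        ux, uz = math.cos(ang), math.sin(ang)
        n_nodes = int(round(basal_length / node_spacing))
        prev = 0
        for k in range(1, n_nodes + 1):
            s = k * node_spacing
            xyz.append([0.6 * s * ux, -0.8 * s, 0.6 * s * uz])
            radius.append(0.5 * d["basal"])
            parent.append(prev)
            ntype.append(BASAL)
            prev = len(xyz) - 1

    # trunk along +y, nodes every node_spacing
    n_trunk = int(round(trunk_length / node_spacing))
    trunk_idx = []
    prev = 0
    for k in range(1, n_trunk + 1):
        y = k * node_spacing
        frac = y / trunk_length
        r = 0.5 * (d["trunk_base"] * (1 - frac) + d["trunk_tip"] * frac)
        xyz.append([0.0, y, 0.0])
        radius.append(r)
        parent.append(prev)
        ntype.append(APICAL)
        prev = len(xyz) - 1
        trunk_idx.append(prev)

    # oblique branches off the trunk, alternating direction in the xz-plane
    for j in range(n_obliques):
        y_origin = first_oblique_um + j * oblique_spacing
        if y_origin > trunk_length - node_spacing:
            break
        origin = trunk_idx[int(round(y_origin / node_spacing)) - 1]
        direction = 1.0 if j % 2 == 0 else -1.0
        tilt = rng.uniform(-0.2, 0.2) if seed is not None else 0.0
        n_nodes = int(round(oblique_length / node_spacing))
        prev = origin
        for k in range(1, n_nodes + 1):
            s = k * node_spacing
            xyz.append([direction * s * math.cos(tilt),
                        xyz[origin][1],
                        s * math.sin(tilt)])
            radius.append(0.5 * d["oblique"])
            parent.append(prev)
            ntype.append(APICAL)
            prev = len(xyz) - 1

    return Morphology(xyz=np.array(xyz), radius=np.array(radius),
                      parent=np.array(parent), ntype=np.array(ntype))
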