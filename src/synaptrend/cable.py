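"""Branched compartmental cable model with passive membrane and a minimal
Hodgkin-Huxley-type spiking mechanism.

The morphology is discretised into frustum compartments; the cable equation
is integrated implicitly (Crank-Nicolson with Hines elimination over the
tree), which is unconditionally stable at the default dt = 0.025 ms.
Synapses are dual-exponential conductances normalised so the peak equals the
requested Gm (the convention of the reference simulator's Exp2Syn object);
the raw difference-of-exponentials form is available behind a flag.

Units: mV, ms, µS, nA, nF; specific quantities in Ω·cm, µF/cm² and S/cm².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .morphology import SOMA, Morphology

__all__ = ["CableParams", "ActiveParams", "ConductanceEvent", "VoltageTrace",
           "CompartmentModel", "discretise", "simulate", "epsp_amplitude",
           "detect_spikes", "exp2syn_peak_factor"]


@dataclass(frozen=True)
class ActiveParams:
    """Na/K channel densities (S/cm²); dendritic densities default to zero.

    The soma compartment lumps the axon initial segment, so its default Na
    density is initial-segment-scale: tuned to fire under strong synaptic
    drive (A = 0.06 µS inputs) with a monotone rate response.
    """

    gna_soma: float = 3.0
    gk_soma: float = 0.8
    gna_dend: float = 0.0    # thin apical branches (obliques)
    gk_dend: float = 0.0
    gna_trunk: float = 0.0   # apical trunk (radius >= 0.6 um)
    gk_trunk: float = 0.0
    ena: float = 50.0
    ek: float = -77.0


@dataclass(frozen=True)
class CableParams:
    """Passive cable parameters.

    Defaults: Ra = 90 Ω·cm and Cm = 1 µF/cm² (the printed "1 mF/cm²" is
    read as a unit typo — 1 mF/cm² is three orders of magnitude off any
    biological membrane); Rm = 28 kΩ·cm²; rest at the −65 mV holding value.
    ``temperature`` is bookkeeping only — channel kinetics are not
    temperature-scaled in this minimal mechanism.
    """

    Ra: float = 90.0          # Ω·cm
    Cm: float = 1.0           # µF/cm²
    g_leak: float = 1.0 / 28000.0   # S/cm²
    E_leak: float = -65.0     # mV
    temperature: float = 34.0  # °C
    active: ActiveParams | None = None
    # dendritic membrane area multiplier folding spines into the cable
    # (standard for spiny pyramidal-cell models; 1.0 = smooth membrane)
    spine_area_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.Ra <= 0 or self.Cm <= 0:
            raise ValueError("Ra and Cm must be positive")


@dataclass(frozen=True)
class ConductanceEvent:
    """One synaptic conductance transient at a compartment."""

    comp: int
    onset_ms: float
    gmax_uS: float
    tau1: float = 1.0     # rise, ms
    tau2: float = 20.0    # decay, ms
    e_rev: float = 0.0    # mV

    def __post_init__(self) -> None:
        if not 0 < self.tau1 < self.tau2:
            raise ValueError("need 0 < tau1 (rise) < tau2 (decay)")


@dataclass
class VoltageTrace:
    """Somatic (and optionally dendritic) voltage over protocol time."""

    time_ms: np.ndarray
    vm_soma: np.ndarray
    dt_ms: float
    recordings: dict = field(default_factory=dict)   # comp index -> trace
    v_final: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd
        cols = {"time_ms": self.time_ms, "vm_soma_mV": self.vm_soma}
        for comp, v in self.recordings.items():
            if comp != 0:
                cols[f"vm_comp{comp}_mV"] = v
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def exp2syn_peak_factor(tau1: float, tau2: float) -> float:
    """Scale factor making the dual-exponential difference peak at 1."""
    tp = tau1 * tau2 / (tau2 - tau1) * math.log(tau2 / tau1)
    return 1.0 / (math.exp(-tp / tau2) - math.exp(-tp / tau1))


# ---------------------------------------------------------------------------
# Discretisation
# ---------------------------------------------------------------------------

@dataclass
class CompartmentModel:
    """Frustum compartments in parent-before-child order (soma/root at 0)."""

    parent: np.ndarray       # (n,) int
    length_um: np.ndarray    # (n,)
    radius_um: np.ndarray    # (n,) midpoint radius
    area_cm2: np.ndarray     # (n,) membrane area
    path0_um: np.ndarray     # (n,) path distance at compartment start
    path1_um: np.ndarray     # (n,) path distance at compartment end
    is_soma: np.ndarray      # (n,) bool
    ntype: np.ndarray        # (n,) SWC type code of the parent morphology node

    @property
    def n(self) -> int:
        return len(self.parent)

    @property
    def path_mid_um(self) -> np.ndarray:
        return 0.5 * (self.path0_um + self.path1_um)

    def axial_conductance_uS(self, Ra: float) -> np.ndarray:
        """Axial conductance between each compartment and its parent (µS)."""
        um = 1e-4  # µm -> cm
        r = self.radius_um * um
        L = self.length_um * um
        half = np.where(self.is_soma,
                        Ra * (self.radius_um * um) / (math.pi * r ** 2),
                        Ra * (L / 2.0) / (math.pi * r ** 2))
        g = np.zeros(self.n)
        for i in range(1, self.n):
            g[i] = 1e6 / (half[i] + half[self.parent[i]])
        return g

    def comp_at_distance(self, x_um: float) -> np.ndarray:
        """Indices of non-soma compartments whose span covers path distance x."""
        return np.flatnonzero((~self.is_soma) & (self.path0_um <= x_um)
                              & (x_um <= self.path1_um))


def _frustum_area_cm2(r1_um: float, r2_um: float, L_um: float) -> float:
    um = 1e-4
    slant = math.sqrt(L_um ** 2 + (r1_um - r2_um) ** 2) * um
    return math.pi * (r1_um + r2_um) * um * slant


def discretise(morph: Morphology, max_seg_len: float = 10.0) -> CompartmentModel:
    """Split every edge of the morphology into compartments ≤ max_seg_len µm.

    Radii taper linearly along each edge, so summed sub-frustum areas equal
    the analytic frustum area of the whole edge.  A soma root becomes a
    spherical compartment; a non-soma root (plain cylinder test geometries)
    contributes no compartment of its own.
    """
    if max_seg_len <= 0:
        raise ValueError("max_seg_len must be positive")
    L_edge = morph.edge_lengths()
    if np.any(L_edge[1:] <= 0):
        raise ValueError("degenerate zero-length section in morphology")
    path = morph.path_distance()

    parent: list[int] = []
    length: list[float] = []
    radius: list[float] = []
    area: list[float] = []
    p0: list[float] = []
    p1: list[float] = []
    soma_flag: list[bool] = []
    ctype: list[int] = []
    comp_of_node = np.full(morph.n_nodes, -1, dtype=int)

    soma_rooted = morph.ntype[0] == SOMA
    if soma_rooted:
        r = morph.radius[0]
        parent.append(-1)
        length.append(2 * r)
        radius.append(r)
        area.append(4.0 * math.pi * (r * 1e-4) ** 2)
        p0.append(0.0)
        p1.append(0.0)
        soma_flag.append(True)
        ctype.append(int(morph.ntype[0]))
        comp_of_node[0] = 0

    n_children = np.zeros(morph.n_nodes, dtype=int)
    for i in range(1, morph.n_nodes):
        n_children[morph.parent[i]] += 1

    for i in range(1, morph.n_nodes):
        pn = morph.parent[i]
        L = L_edge[i]
        # radius tapers from the parent node within an unbranched same-type
        # chain; at branch points (and leaving the soma sphere) the child
        # branch keeps its own calibre — a thin oblique must not inherit a
        # conical stub of the thick trunk it leaves
        chain = (n_children[pn] == 1 and morph.ntype[pn] == morph.ntype[i]
                 and not (pn == 0 and soma_rooted))
        r_a = morph.radius[pn] if chain else morph.radius[i]
        r_b = morph.radius[i]
        k = max(1, int(math.ceil(L / max_seg_len - 1e-9)))
        seg_len = L / k
        prev_comp = comp_of_node[pn]
        d_start = path[pn]
        for s in range(k):
            f0, f1 = s / k, (s + 1) / k
            r1 = r_a * (1 - f0) + r_b * f0
            r2 = r_a * (1 - f1) + r_b * f1
            parent.append(prev_comp)
            length.append(seg_len)
            radius.append(0.5 * (r1 + r2))
            area.append(_frustum_area_cm2(r1, r2, seg_len))
            p0.append(d_start + s * seg_len)
            p1.append(d_start + (s + 1) * seg_len)
            soma_flag.append(False)
            ctype.append(int(morph.ntype[i]))
            prev_comp = len(parent) - 1
        comp_of_node[i] = prev_comp

    if not soma_rooted and parent and parent[0] == -1:
        pass  # first created compartment is the root
    return CompartmentModel(parent=np.array(parent, dtype=np.int64),
                            length_um=np.array(length),
                            radius_um=np.array(radius),
                            area_cm2=np.array(area),
                            path0_um=np.array(p0), path1_um=np.array(p1),
                            is_soma=np.array(soma_flag, dtype=bool),
                            ntype=np.array(ctype, dtype=int))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(comps: CompartmentModel,
             params: CableParams,
             events,
             duration_ms: float,
             dt: float = 0.025,
             stabilise_ms: float = 300.0,
             record_comps=(),
             iclamp=None,
             exp2syn_normalise: bool = True) -> VoltageTrace:
    """Integrate the cable; event onsets are in protocol time (t = 0 after
    ``stabilise_ms`` of event-free settling).

    ``iclamp`` is an optional sequence of (comp, nA) constant current
    injections active for the whole simulation.  All events must share one
    kinetic scheme (tau1, tau2, e_rev).  Raises on numerical divergence.
    """
    events = list(events)
    if events:
        tau1 = events[0].tau1
        tau2 = events[0].tau2
        e_syn = events[0].e_rev
        for ev in events:
            if (ev.tau1, ev.tau2, ev.e_rev) != (tau1, tau2, e_syn):
                raise ValueError("all events in one run must share kinetics")
        if dt > tau1 / 4.0:
            raise ValueError("dt must not exceed tau1/4")
    else:
        tau1, tau2, e_syn = 1.0, 20.0, 0.0

    n = comps.n
    area = comps.area_cm2 * np.where(comps.is_soma, 1.0, params.spine_area_scale)
    cdt = params.Cm * area * 1e3 / dt                    # µF -> nF, / ms
    gpas = params.g_leak * area * 1e6                    # S -> µS
    gax = comps.axial_conductance_uS(params.Ra)
    gna = np.zeros(n)
    gk = np.zeros(n)
    ena, ek = 50.0, -77.0
    if params.active is not None:
        a = params.active
        apical = (~comps.is_soma) & (comps.ntype == 4)
        trunk = apical & (comps.radius_um >= 0.6)
        thin = apical & ~trunk
        dens_na = (np.where(comps.is_soma, a.gna_soma, 0.0)
                   + np.where(thin, a.gna_dend, 0.0)
                   + np.where(trunk, a.gna_trunk, 0.0))
        dens_k = (np.where(comps.is_soma, a.gk_soma, 0.0)
                  + np.where(thin, a.gk_dend, 0.0)
                  + np.where(trunk, a.gk_trunk, 0.0))
        gna = dens_na * comps.area_cm2 * 1e6
        gk = dens_k * comps.area_cm2 * 1e6
        ena, ek = a.ena, a.ek

    n_steps = int(round((stabilise_ms + duration_ms) / dt))
    rec_start = int(round(stabilise_ms / dt))

    factor = exp2syn_peak_factor(tau1, tau2) if (events and exp2syn_normalise) else 1.0
    ev_sorted = sorted(events, key=lambda e: e.onset_ms)
    ev_step = np.array([int(round((stabilise_ms + e.onset_ms) / dt)) for e in ev_sorted],
                       dtype=np.int64)
    ev_comp = np.array([e.comp for e in ev_sorted], dtype=np.int64)
    ev_w = np.array([e.gmax_uS * factor for e in ev_sorted])
    if len(ev_step) and (ev_step.min() < 0 or ev_step.max() >= n_steps):
        raise ValueError("event onset outside the simulated window")

    iinj = np.zeros(n)
    if iclamp:
        for comp, amp in iclamp:
            iinj[comp] += amp

    rec_idx = np.unique(np.array([0] + [int(c) for c in record_comps],
                                 dtype=np.int64))

    from . import _kernels  # deferred: triggers numba compilation on first use
    out, v_final = _kernels.integrate(
        comps.parent, gax, cdt, gpas, params.E_leak, gna, gk, ena, ek,
        n_steps, dt, params.E_leak,
        ev_step, ev_comp, ev_w,
        math.exp(-dt / tau1), math.exp(-dt / tau2), e_syn,
        iinj, rec_idx, rec_start)

    if not np.all(np.isfinite(v_final)):
        raise RuntimeError("numerical divergence: non-finite membrane voltage "
                           f"(dt={dt}, n_comps={n})")

    time = np.arange(out.shape[1]) * dt
    recordings = {int(c): out[r] for r, c in enumerate(rec_idx)}
    return VoltageTrace(time_ms=time, vm_soma=recordings[0], dt_ms=dt,
                        recordings=recordings, v_final=v_final)


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

def epsp_amplitude(trace: VoltageTrace, stim_onset: float, window: float,
                   baseline_time: float | None = None,
                   spike_threshold: float = 0.0) -> tuple[float, bool]:
    """EPSP amplitude: window peak minus the baseline voltage.

    The baseline defaults to the voltage at the stimulus onset
    (onset-subtracted convention — appropriate for a second pulse riding on
    the first); pass ``baseline_time=0`` to subtract the pre-protocol rest.
    Returns (amplitude mV, spike_flag); a threshold crossing inside the
    window invalidates the EPSP measure.
    """
    t = trace.time_ms
    if stim_onset + window > t[-1] + 1e-9:
        raise ValueError("measurement window extends past the trace")
    bt = stim_onset if baseline_time is None else baseline_time
    i_base = int(np.searchsorted(t, bt))
    i_base = min(max(i_base, 0), len(t) - 1)
    sel = (t >= stim_onset) & (t <= stim_onset + window)
    peak = float(np.max(trace.vm_soma[sel]))
    spiked = peak >= spike_threshold
    return peak - float(trace.vm_soma[i_base]), spiked


def detect_spikes(trace: VoltageTrace, threshold: float = 0.0,
                  refractory_ms: float = 2.0) -> np.ndarray:
    """Times of upward threshold crossings, merged within a refractory gap."""
    v = trace.vm_soma
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = trace.time_ms[crossings]
    if len(times) == 0:
        return times
    keep = [times[0]]
    for tt in times[1:]:
        if tt - keep[-1] >= refractory_ms:
            keep.append(tt)
    return np.array(keep)
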