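"""In-silico protocols probing how the centrifugal release-probability trend
shapes somatic integration.

Three protocols on a cell with 50 stochastic synapses:

* ``paired_pulse`` — synchronous paired stimuli 50 ms apart at subthreshold
  conductance scale (A = 0.002 µS); per-run EPSP amplitudes and PPR.
* ``burst5`` — five stimuli at 20 Hz with the short-term-plasticity engine
  driving per-pulse release probabilities; the voltage-transfer metric is the
  time-integral of somatic depolarisation over the burst (mV·ms).
* ``poisson`` — independent Poisson afferent trains per synapse at spiking
  scale (A = 0.06 µS); input-output firing-rate curves.

Conditions share per-run placement and release random numbers (the random
seed is kept unchanged across compared conditions), so uniform-vs-trend
contrasts are paired by construction.  Synapse placement is regenerated anew
for every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import synapses as syn
from .cable import (ActiveParams, CableParams, CompartmentModel,
                    ConductanceEvent, detect_spikes, discretise,
                    epsp_amplitude, simulate)
from .quantal import compare_paired
from .synthetic import BURST_SLOPE_PROFILE, generate_morphology

__all__ = ["ExperimentConfig", "ProtocolResult", "default_cell",
           "run_paired_pulse", "run_burst5", "run_io_curve",
           "run_condition_comparison", "summarise",
           "plot_io_curves", "plot_condition_summary"]

CONDITIONS = ("uniform", "pr_trend", "pr_and_density_trend")


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol configuration; compared conditions must share master_seed."""

    condition: str = "uniform"
    n_runs: int = 100
    protocol: str = "paired_pulse"
    A: float = 0.002                  # µS; 0.06 for spiking protocols
    input_rate: float = 10.0          # Hz per axon (poisson protocol)
    stp: bool = False
    stp_params: syn.STPParams = field(default_factory=syn.STPParams)
    stp_consistency: bool = True      # calibrate STP to the 50-ms P2 field
    # burst release model: the measured five-pulse slope trend, or the
    # calibrated STP engine
    burst_release: str = "slope_trend"
    master_seed: int = 0
    n_synapses: int = 50
    rescale_mean: bool = False        # True: force mean P1 to 0.36 in trend mode
    dt: float = 0.025
    stabilise_ms: float = 300.0
    io_duration_ms: float = 2000.0
    active: ActiveParams | None = None
    # force every synapse's P1 and P2 to a fixed value (degenerate/placebo tests)
    pr_override: float | None = None
    # synapses sit on oblique branches, not the apical trunk
    synapse_max_radius_um: float | None = 0.55
    # dendritic spine membrane folded into the cable
    spine_area_scale: float = 3.0

    def to_yaml(self, path) -> None:
        import dataclasses

        import yaml
        d = dataclasses.asdict(self)
        d["stp_params"] = dataclasses.asdict(self.stp_params)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "stp_params" in d and isinstance(d["stp_params"], dict):
            d["stp_params"] = syn.STPParams(**d["stp_params"])
        if d.get("active") is not None and isinstance(d["active"], dict):
            d["active"] = ActiveParams(**d["active"])
        return cls(**d)

    def modes(self) -> tuple[str, str]:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        pr_mode = "uniform" if self.condition == "uniform" else "trend"
        density_mode = "trend" if self.condition == "pr_and_density_trend" else "uniform"
        return pr_mode, density_mode


@dataclass
class ProtocolResult:
    """Per-run table plus condition-level summary for one protocol."""

    protocol: str
    condition: str
    per_run: pd.DataFrame
    summary: dict

    @property
    def n_valid(self) -> int:
        return int((~self.per_run["flagged"]).sum())


def default_cell(max_seg_len: float = 10.0, seed: int | None = None) -> CompartmentModel:
    """Discretised synthetic apical-tree cell used by all protocols."""
    return discretise(generate_morphology(seed=seed), max_seg_len)


def _run_seeds(master_seed: int, run: int, stream: int) -> list[int]:
    # per-run, per-stream seeds shared across conditions (matched comparisons)
    return [int(master_seed) % (2 ** 31), run, stream]


def _place(config: ExperimentConfig, comps: CompartmentModel, run: int):
    pr_mode, density_mode = config.modes()
    pop = syn.place_synapses(
        comps, n=config.n_synapses, density_mode=density_mode, pr_mode=pr_mode,
        A=config.A, rescale_mean=(config.rescale_mean and pr_mode == "trend"),
        max_radius_um=config.synapse_max_radius_um,
        seed=_run_seeds(config.master_seed, run, 0))
    if config.pr_override is not None:
        pop.P1 = np.full(pop.n, config.pr_override)
        pop.P2 = np.full(pop.n, config.pr_override)
    return pop


def _mean_sem(v: np.ndarray) -> tuple[float, float]:
    v = np.asarray(v, dtype=float)
    if len(v) == 0:
        return float("nan"), float("nan")
    sem = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
    return float(np.mean(v)), sem


# ---------------------------------------------------------------------------
# Paired pulse
# ---------------------------------------------------------------------------

def run_paired_pulse(config: ExperimentConfig,
                     comps: CompartmentModel | None = None) -> ProtocolResult:
    """Synchronous paired-pulse runs; EPSP1/EPSP2/PPR per run.

    EPSP1 is the somatic peak minus the pre-protocol rest; EPSP2 subtracts
    the voltage at the second-pulse onset (both conventions are recorded).
    Runs producing a somatic spike at this subthreshold scale are flagged
    and excluded from summaries.
    """
    comps = comps if comps is not None else default_cell()
    params = CableParams(active=config.active,
                         spine_area_scale=config.spine_area_scale)
    t1, t2 = 20.0, 70.0
    duration = 160.0
    rows = []
    for r in range(config.n_runs):
        pop = _place(config, comps, r)
        rng = np.random.default_rng(_run_seeds(config.master_seed, r, 1))
        rel1, rel2 = syn.sample_paired_release(pop, rng=rng)
        events = [ConductanceEvent(comp=int(c), onset_ms=t1, gmax_uS=float(g))
                  for c, g in zip(pop.comp[rel1], pop.Gm_uS[rel1])]
        events += [ConductanceEvent(comp=int(c), onset_ms=t2, gmax_uS=float(g))
                   for c, g in zip(pop.comp[rel2], pop.Gm_uS[rel2])]
        trace = simulate(comps, params, events, duration, dt=config.dt,
                         stabilise_ms=config.stabilise_ms)
        e1, sp1 = epsp_amplitude(trace, t1, t2 - t1 - 1.0, baseline_time=0.0)
        e2, sp2 = epsp_amplitude(trace, t2, 45.0)                 # onset-subtracted
        e2_abs, _ = epsp_amplitude(trace, t2, 45.0, baseline_time=0.0)
        flagged = bool(sp1 or sp2)
        ppr = e2 / e1 if (e1 > 1e-6 and not flagged) else np.nan
        rows.append({"run": r, "epsp1_mV": e1, "epsp2_mV": e2,
                     "epsp2_abs_mV": e2_abs, "ppr": ppr,
                     "n_rel1": int(rel1.sum()), "n_rel2": int(rel2.sum()),
                     "flagged": flagged})
    per_run = pd.DataFrame(rows)
    ok = per_run[~per_run["flagged"]]
    m1, s1 = _mean_sem(ok["epsp1_mV"])
    m2, s2 = _mean_sem(ok["epsp2_mV"])
    mp, sp = _mean_sem(ok["ppr"].dropna())
    summary = {"condition": config.condition, "n": len(ok),
               "epsp1_mean": m1, "epsp1_sem": s1,
               "epsp2_mean": m2, "epsp2_sem": s2,
               "ppr_mean": mp, "ppr_sem": sp}
    return ProtocolResult("paired_pulse", config.condition, per_run, summary)


# ---------------------------------------------------------------------------
# Five-pulse burst
# ---------------------------------------------------------------------------

def run_burst5(config: ExperimentConfig,
               comps: CompartmentModel | None = None) -> ProtocolResult:
    """Five-pulse 20 Hz burst runs with STP-driven release probabilities.

    The per-synapse engine is calibrated so its 50-ms paired-pulse
    prediction matches the synapse's P2 field (consistency mode), then
    evolved over the five stimuli; the voltage-transfer metric integrates
    somatic depolarisation from the first stimulus to 50 ms past the last.
    """
    comps = comps if comps is not None else default_cell()
    params = CableParams(active=config.active,
                         spine_area_scale=config.spine_area_scale)
    stim_times = [20.0 + 50.0 * k for k in range(5)]
    duration = stim_times[-1] + 100.0
    rows = []
    for r in range(config.n_runs):
        pop = _place(config, comps, r)
        rng = np.random.default_rng(_run_seeds(config.master_seed, r, 1))
        pr_mode, _ = config.modes()
        events = []
        for i in range(pop.n):
            if config.burst_release == "slope_trend":
                # per-pulse release follows the five-pulse facilitation-slope
                # profile; the uniform condition carries the same mean slope
                # without distance dependence
                sa, sb = BURST_SLOPE_PROFILE
                x_eff = pop.x_um[i] if pr_mode == "trend" else 195.0
                s = sb + sa * x_eff
                probs = np.clip(pop.P1[i] * (1.0 + s * np.arange(5)), 0.01, 0.99)
            elif config.burst_release == "stp_engine":
                target = pop.P2[i] / max(pop.P1[i], 1e-12)
                sp = (syn.calibrate_stp_to_ppr(target, config.stp_params)
                      if config.stp_consistency else config.stp_params)
                probs = syn.stp_evolve(stim_times, float(pop.P1[i]), sp)
            else:
                raise ValueError(f"unknown burst release model {config.burst_release!r}")
            u = rng.random(5)
            for k, (p, s) in enumerate(zip(probs, stim_times)):
                if u[k] < p:
                    events.append(ConductanceEvent(comp=int(pop.comp[i]),
                                                   onset_ms=s,
                                                   gmax_uS=float(pop.Gm_uS[i])))
        trace = simulate(comps, params, events, duration, dt=config.dt,
                         stabilise_ms=config.stabilise_ms)
        sel = (trace.time_ms >= stim_times[0]) & (trace.time_ms <= stim_times[-1] + 50.0)
        v0 = float(trace.vm_soma[trace.time_ms < stim_times[0]].mean())
        transfer = float(np.trapezoid(trace.vm_soma[sel] - v0,
                                      trace.time_ms[sel]))
        peak = float(np.max(trace.vm_soma[sel]) - v0)
        flagged = bool(np.max(trace.vm_soma[sel]) >= 0.0)
        rows.append({"run": r, "transfer_mVms": transfer, "peak_mV": peak,
                     "n_events": len(events), "flagged": flagged})
    per_run = pd.DataFrame(rows)
    ok = per_run[~per_run["flagged"]]
    mt, st = _mean_sem(ok["transfer_mVms"])
    summary = {"condition": config.condition, "n": len(ok),
               "transfer_mean": mt, "transfer_sem": st}
    return ProtocolResult("burst5", config.condition, per_run, summary)


# ---------------------------------------------------------------------------
# Poisson-drive input-output curves
# ---------------------------------------------------------------------------

def run_io_curve(config: ExperimentConfig, rates,
                 comps: CompartmentModel | None = None) -> pd.DataFrame:
    """Output spike rate vs per-axon Poisson input rate for one condition.

    Every synapse receives an independent Poisson train; with ``config.stp``
    the release probability of each spike follows the STP engine, otherwise
    it stays at the synapse's P1.  Active soma channels must be enabled
    (they are by default here) for a spiking readout.
    """
    comps = comps if comps is not None else default_cell()
    active = config.active if config.active is not None else ActiveParams()
    params = CableParams(active=active,
                         spine_area_scale=config.spine_area_scale)
    duration = config.io_duration_ms
    out_rows = []
    for rate in rates:
        rate_key = int(round(rate * 1000))
        run_rates = []
        for r in range(config.n_runs):
            pop = _place(config, comps, r)
            rng_train = np.random.default_rng(
                _run_seeds(config.master_seed, r, 2) + [rate_key])
            rng_rel = np.random.default_rng(
                _run_seeds(config.master_seed, r, 3) + [rate_key])
            events = []
            for i in range(pop.n):
                train = syn.poisson_train(rate, duration - 60.0, rng=rng_train) + 10.0
                if len(train) == 0:
                    continue
                if config.stp:
                    sp = (syn.calibrate_stp_to_ppr(
                            pop.P2[i] / max(pop.P1[i], 1e-12), config.stp_params)
                          if config.stp_consistency else config.stp_params)
                    probs = syn.stp_evolve(train, float(pop.P1[i]), sp)
                else:
                    probs = np.full(len(train), pop.P1[i])
                u = rng_rel.random(len(train))
                for t_spk, p, uu in zip(train, probs, u):
                    if uu < p:
                        events.append(ConductanceEvent(comp=int(pop.comp[i]),
                                                       onset_ms=float(t_spk),
                                                       gmax_uS=float(pop.Gm_uS[i])))
            if events:
                trace = simulate(comps, params, events, duration, dt=config.dt,
                                 stabilise_ms=config.stabilise_ms)
                n_spk = len(detect_spikes(trace))
            else:
                n_spk = 0
            run_rates.append(n_spk / (duration / 1000.0))
        m, s = _mean_sem(np.array(run_rates))
        out_rows.append({"condition": config.condition, "stp": config.stp,
                         "rate_in_hz": float(rate), "rate_out_hz": m,
                         "rate_out_sem": s, "n_runs": config.n_runs})
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# Comparison and reporting
# ---------------------------------------------------------------------------

def run_condition_comparison(protocol: str, conditions=("uniform", "pr_trend"),
                             comps: CompartmentModel | None = None,
                             rates=None, **config_kwargs) -> dict:
    """Run one protocol under several conditions at matched seeds."""
    comps = comps if comps is not None else default_cell()
    results = {}
    for cond in conditions:
        cfg = ExperimentConfig(condition=cond, protocol=protocol, **config_kwargs)
        if protocol == "paired_pulse":
            results[cond] = run_paired_pulse(cfg, comps)
        elif protocol == "burst5":
            results[cond] = run_burst5(cfg, comps)
        elif protocol == "poisson":
            results[cond] = run_io_curve(cfg, rates, comps)
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
    return results


def summarise(results: dict, test: str = "t",
              metric: str | None = None, reference: str = "uniform") -> pd.DataFrame:
    """Condition summaries with percentage differences and paired p-values.

    ``results`` maps condition name to :class:`ProtocolResult` from runs at
    matched seeds; differences are relative to ``reference``.
    """
    if reference not in results:
        raise ValueError(f"reference condition {reference!r} missing")
    ref = results[reference]
    metrics = ([metric] if metric else
               (["epsp1_mV", "ppr"] if ref.protocol == "paired_pulse"
                else ["transfer_mVms"]))
    n_ref = len(ref.per_run)
    rows = []
    for cond, res in results.items():
        if len(res.per_run) != n_ref:
            raise ValueError("mismatched run counts between conditions")
        for m in metrics:
            a = res.per_run[m].to_numpy(dtype=float)
            b = ref.per_run[m].to_numpy(dtype=float)
            valid = (~res.per_run["flagged"] & ~ref.per_run["flagged"]
                     & np.isfinite(a) & np.isfinite(b))
            a, b = a[valid.to_numpy()], b[valid.to_numpy()]
            mean, sem = _mean_sem(a)
            ref_mean, _ = _mean_sem(b)
            pct = 100.0 * (mean - ref_mean) / ref_mean if ref_mean else np.nan
            if cond == reference:
                p = 1.0
            else:
                p = compare_paired(a, b, test=test)
            rows.append({"condition": cond, "metric": m, "n": len(a),
                         "mean": mean, "sem": sem,
                         "pct_diff_vs_ref": pct, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def plot_io_curves(io_frames, path) -> None:
    """Input-output firing-rate figure for one or more conditions.

    ``io_frames`` maps condition name to a frame from :func:`run_io_curve`.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for cond, df in io_frames.items():
        ax.errorbar(df["rate_in_hz"], df["rate_out_hz"], yerr=df["rate_out_sem"],
                    marker="o", capsize=3, label=cond)
    ax.set_xlabel("input rate per axon (Hz)")
    ax.set_ylabel("output spike rate (Hz)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_condition_summary(results: dict, metric: str, path) -> None:
    """Bar-and-dots figure of a per-run metric across conditions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.0, 3.5))
    for i, (cond, res) in enumerate(results.items()):
        ok = res.per_run[~res.per_run["flagged"]]
        v = ok[metric].dropna().to_numpy(dtype=float)
        ax.bar(i, v.mean(), width=0.6, alpha=0.4)
        ax.plot(np.full(len(v), i) + np.random.default_rng(0).uniform(-0.15, 0.15, len(v)),
                v, ".", ms=4, alpha=0.6)
    ax.set_xticks(range(len(results)))
    ax.set_xticklabels(list(results))
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
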