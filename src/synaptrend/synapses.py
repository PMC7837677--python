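"""Stochastic synapse populations on a morphology.

Fifty excitatory synapses (default) are scattered over the apical tree
between 40 and 350 µm path distance from the soma, either uniformly or
following the experimentally observed density trend.  Each synapse carries a
peak conductance Gm ∝ A·(0.51 + 0.002·x) (receptor numbers growing
centrifugally), and release probabilities that are either uniform
(P1 = 0.36, P2 = 0.77) or follow the distance regressions
P1(x) = 0.18 + 0.0012·x and P2(x) = P1(x)·(3.31 − 0.0074·x).

For spike trains a short-term-plasticity engine evolves per-spike release
probabilities: a multiplicative facilitation factor F and a depression
resource R (both relaxing exponentially between spikes) give
p_k = base_P·F_k·R_k, so an isolated spike releases with exactly base_P.
The engine's paired-pulse prediction can be calibrated per synapse, in
closed form, to match the 50-ms PPR field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cable import CompartmentModel

__all__ = ["SynapsePopulation", "STPParams", "place_synapses", "pr_profile",
           "p2_profile", "gm_profile", "sample_paired_release", "stp_evolve",
           "calibrate_stp_to_ppr", "stp_steady_scale", "poisson_train",
           "release_log_frame", "MEAN_P1", "MEAN_P2"]

MEAN_P1 = 0.36
MEAN_P2 = 0.77
X_RANGE_DEFAULT = (40.0, 350.0)


# ---------------------------------------------------------------------------
# Distance profiles
# ---------------------------------------------------------------------------

def pr_profile(x, mode: str = "trend", rescale_mean: bool = False,
               x_range=X_RANGE_DEFAULT):
    """First-pulse release probability at path distance x (µm).

    ``trend``: P1(x) = 0.18 + 0.0012·x, clipped to [0, 1]; with
    ``rescale_mean`` the profile is multiplied by the constant that makes its
    mean over a uniform x on ``x_range`` exactly 0.36 (the literal regression
    averages to ≈0.414 over 40-350 µm).  ``uniform``: 0.36 everywhere.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("distance must be non-negative")
    if mode == "uniform":
        return np.broadcast_to(np.float64(MEAN_P1), x.shape).copy() if x.ndim else float(MEAN_P1)
    if mode != "trend":
        raise ValueError(f"unknown mode {mode!r}")
    p = 0.18 + 0.0012 * x
    if rescale_mean:
        p = p * _trend_rescale_factor(x_range)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def _trend_rescale_factor(x_range=X_RANGE_DEFAULT) -> float:
    lo, hi = x_range
    mean_literal = 0.18 + 0.0012 * (lo + hi) / 2.0
    return MEAN_P1 / mean_literal


def ppr_profile_value(x):
    """Paired-pulse ratio regression PPR(x) = 3.31 − 0.0074·x."""
    return 3.31 - 0.0074 * np.asarray(x, dtype=float)


def p2_profile(x, mode: str = "trend", rescale_mean: bool = False,
               x_range=X_RANGE_DEFAULT):
    """Second-pulse release probability at path distance x (µm).

    ``trend``: P2(x) = (0.18 + 0.0012·x)·(3.31 − 0.0074·x), clipped to
    [0, 1].  ``rescale_mean`` applies the same factor as :func:`pr_profile`
    so the PPR regression — the measured quantity — is preserved.
    ``uniform``: 0.77 everywhere.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("distance must be non-negative")
    if mode == "uniform":
        return np.broadcast_to(np.float64(MEAN_P2), x.shape).copy() if x.ndim else float(MEAN_P2)
    if mode != "trend":
        raise ValueError(f"unknown mode {mode!r}")
    p = (0.18 + 0.0012 * x) * ppr_profile_value(x)
    if rescale_mean:
        p = p * _trend_rescale_factor(x_range)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def gm_profile(x, A: float):
    """Peak synaptic conductance Gm(x) = A·(0.51 + 0.002·x) in µS.

    A = 0.002 µS for subthreshold protocols, 0.06 µS for spiking protocols.
    """
    if A <= 0:
        raise ValueError("scale A must be positive")
    g = A * (0.51 + 0.002 * np.asarray(x, dtype=float))
    return float(g) if g.ndim == 0 else g


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

@dataclass
class SynapsePopulation:
    """Per-synapse state for one placement of the stochastic inputs."""

    comp: np.ndarray        # compartment index per synapse
    x_um: np.ndarray        # path distance to soma
    Gm_uS: np.ndarray
    P1: np.ndarray
    P2: np.ndarray
    pr_mode: str = "trend"
    density_mode: str = "uniform"
    A_uS: float = 0.002
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.x_um)


def _sample_positions(rng, n: int, x_range, density_mode: str,
                      density_slope: float) -> np.ndarray:
    lo, hi = x_range
    if density_mode == "uniform":
        return rng.uniform(lo, hi, size=n)
    if density_mode != "trend":
        raise ValueError(f"unknown density mode {density_mode!r}")
    # linear density f(x) ∝ 1 + density_slope·(x − lo); inverse-CDF sampling
    span = hi - lo
    b = density_slope
    u = rng.random(n)
    if b == 0:
        return lo + u * span
    # CDF(x) = (s + b s²/2)/(span + b span²/2), s = x − lo
    norm = span + 0.5 * b * span * span
    s = (-1.0 + np.sqrt(1.0 + 2.0 * b * u * norm)) / b
    return lo + s


def place_synapses(comps: CompartmentModel,
                   n: int = 50,
                   x_range=X_RANGE_DEFAULT,
                   density_mode: str = "uniform",
                   pr_mode: str = "trend",
                   A: float = 0.002,
                   rescale_mean: bool = False,
                   density_slope: float = 0.004,
                   max_radius_um: float | None = None,
                   seed: int | None = None) -> SynapsePopulation:
    """Scatter ``n`` synapses over the tree within ``x_range`` path distance.

    Positions are i.i.d. in path distance from either a uniform density or a
    linear centrifugally increasing density (default slope doubles the
    density over 40-350 µm, emulating the observed spine-density trend); when
    several branches span the sampled distance one is chosen uniformly.
    ``max_radius_um`` restricts placement to thin branches (Schaffer
    synapses sit on oblique dendrites, not the apical trunk).  Placement is
    regenerated anew for every trial seed.
    """
    lo, hi = x_range
    reach = float(np.max(comps.path1_um))
    if hi > reach + 1e-9:
        raise ValueError(f"morphology reaches {reach:.1f} µm; cannot place at {hi} µm")
    rng = np.random.default_rng(seed)
    if n == 0:
        z = np.zeros(0)
        return SynapsePopulation(comp=z.astype(int), x_um=z, Gm_uS=z, P1=z, P2=z,
                                 pr_mode=pr_mode, density_mode=density_mode,
                                 A_uS=A, seed=seed)
    xs = _sample_positions(rng, n, x_range, density_mode, density_slope)
    comp_idx = np.empty(n, dtype=int)
    for i, x in enumerate(xs):
        cands = comps.comp_at_distance(float(x))
        if max_radius_um is not None:
            thin = cands[comps.radius_um[cands] <= max_radius_um]
            cands = thin if len(thin) else cands
        if len(cands) == 0:
            raise ValueError(f"no compartment spans path distance {x:.1f} µm")
        comp_idx[i] = cands[rng.integers(len(cands))]
    p1 = np.atleast_1d(pr_profile(xs, mode=pr_mode, rescale_mean=rescale_mean,
                                  x_range=x_range))
    p2 = np.atleast_1d(p2_profile(xs, mode=pr_mode, rescale_mean=rescale_mean,
                                  x_range=x_range))
    if rescale_mean and pr_mode == "trend":
        # enforce the exact realised-population mean, not just the expectation;
        # P2 gets the same factor so the PPR(x) regression is preserved
        factor = MEAN_P1 / p1.mean()
        p1 = np.clip(p1 * factor, 0.0, 1.0)
        p2 = np.clip(p2 * factor, 0.0, 1.0)
    gm = np.atleast_1d(gm_profile(xs, A))
    return SynapsePopulation(comp=comp_idx, x_um=xs, Gm_uS=gm, P1=p1, P2=p2,
                             pr_mode=pr_mode, density_mode=density_mode,
                             A_uS=A, seed=seed)


def sample_paired_release(pop: SynapsePopulation, seed: int | None = None,
                          rng: np.random.Generator | None = None,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-synapse Bernoulli release flags for a paired-pulse trial.

    Pulse 1 uses P1, pulse 2 the marginal P2, independently across synapses
    and pulses (only the marginal second-pulse probability is specified
    experimentally).  Common random numbers across compared conditions come
    from passing the same seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    u1 = rng.random(pop.n)
    u2 = rng.random(pop.n)
    return u1 < pop.P1, u2 < pop.P2


# ---------------------------------------------------------------------------
# Short-term plasticity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class STPParams:
    """Facilitation/depression engine parameters.

    ``U`` is the baseline utilisation (fraction of resources consumed by an
    isolated release); ``facil_increment`` is the jump of the multiplicative
    facilitation factor per spike; time constants in ms.  Defaults give
    prominent facilitation/depression over the first 2-4 spikes of a train
    and a near-constant frequency-dependent steady state thereafter.
    """

    U: float = 0.36
    facil_increment: float = 1.2
    tau_facil: float = 35.0
    tau_rec: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.U <= 1:
            raise ValueError("U must be in (0, 1]")
        if self.tau_facil < 0 or self.tau_rec < 0:
            raise ValueError("time constants must be non-negative")


def stp_evolve(spike_times, base_P: float, params: STPParams) -> np.ndarray:
    """Per-spike release probabilities along a (sorted) spike train.

    p_k = base_P·F_k·R_k (clipped to 1), with F relaxing to 1 with
    ``tau_facil`` and jumping by ``facil_increment·base`` after each spike,
    and the resource R recovering to 1 with ``tau_rec`` after being depleted
    by each release.  A single spike returns exactly ``base_P``.
    """
    st = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(st) < 0):
        raise ValueError("spike times must be sorted")
    F, R = 1.0, 1.0
    last = None
    out = np.empty(len(st))
    for k, t in enumerate(st):
        if last is not None:
            dt = t - last
            ef = math.exp(-dt / params.tau_facil) if params.tau_facil > 0 else 0.0
            er = math.exp(-dt / params.tau_rec) if params.tau_rec > 0 else 0.0
            F = 1.0 + (F - 1.0) * ef
            R = 1.0 - (1.0 - R) * er
        p = min(1.0, base_P * F * R)
        out[k] = p
        # post-spike updates: facilitation jump, utilisation-driven depletion
        u = min(1.0, params.U * F)
        F = F + params.facil_increment
        R = R * (1.0 - u)
        last = t
    return out


def calibrate_stp_to_ppr(target_ppr: float, params: STPParams,
                         dt_ms: float = 50.0) -> STPParams:
    """Closed-form per-synapse calibration of the facilitation increment so
    the engine's paired-pulse prediction at ``dt_ms`` equals ``target_ppr``.

    After one spike (p1 = base_P), the second-spike prediction is
    p2/p1 = F2·R2 with F2 = 1 + φ·exp(−Δt/τ_f) and R2 = 1 − U·exp(−Δt/τ_r);
    solving for φ is exact.
    """
    ef = math.exp(-dt_ms / params.tau_facil) if params.tau_facil > 0 else 0.0
    er = math.exp(-dt_ms / params.tau_rec) if params.tau_rec > 0 else 0.0
    r2 = 1.0 - params.U * er
    if ef == 0:
        raise ValueError("cannot calibrate with tau_facil = 0")
    phi = (target_ppr / r2 - 1.0) / ef
    if phi < 0:
        phi = 0.0
    return replace(params, facil_increment=phi)


def stp_steady_scale(rate_hz: float, base_P: float, params: STPParams,
                     n_spikes: int = 200) -> float:
    """Steady-state p/base_P for a constant-rate train (numerical fixed point)."""
    if rate_hz <= 0:
        return 1.0
    times = np.arange(n_spikes) * (1000.0 / rate_hz)
    p = stp_evolve(times, base_P, params)
    return float(p[-1] / base_P)


# ---------------------------------------------------------------------------
# Afferent drive
# ---------------------------------------------------------------------------

def poisson_train(rate_hz: float, duration_ms: float,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Homogeneous Poisson spike train on [0, duration_ms)."""
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    if rate_hz == 0:
        return np.zeros(0)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    return np.sort(rng.uniform(0.0, duration_ms, size=n))


def release_log_frame(pop: SynapsePopulation, trial: int,
                      rel1, rel2) -> pd.DataFrame:
    """Tidy event log of one paired-pulse trial (one row per synapse+pulse)."""
    rows = []
    for pulse, rel in ((1, rel1), (2, rel2)):
        for i in range(pop.n):
            rows.append({"trial": trial, "synapse": i, "pulse": pulse,
                         "released": bool(rel[i]), "x_um": float(pop.x_um[i])})
    return pd.DataFrame(rows)
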