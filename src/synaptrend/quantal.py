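"""Optical quantal analysis: release-probability estimators and trend statistics.

Single-synapse optical quantal analysis (OQA) scores each paired-pulse trial at
a dendritic spine as a success (1) or failure (0) per pulse, based on whether a
postsynaptic Ca2+ transient exceeds a noise criterion.  From the four outcome
counts (0,0), (0,1), (1,0), (1,1) over N trials the release probabilities are

    P1  = (n10 + n11) / N            first-pulse release probability (= Pr)
    P2  = (n01 + n11) / N            second-pulse release probability
    P2* = n01 / (n00 + n01)          second-pulse probability conditioned on
                                     first-pulse failure
    PPR = P2 / P1,  PPR* = P2* / P1  paired-pulse ratios

P2* sidesteps uncertainty in detecting a second success on top of a first
(indicator saturation): trials with a first-pulse success are simply ignored.

The trend statistics relate per-synapse estimates to dendritic position:
ordinary least-squares regression with the slope t-test and Pearson's r,
distance binning (pooling), within-branch pairwise differences, relative
branch position, and local spine density.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrialOutcome",
    "PairedCounts",
    "QuantalEstimates",
    "RegressionResult",
    "classify_trial",
    "classify_trials",
    "count_outcomes",
    "estimate_release",
    "regress_trend",
    "bin_and_pool",
    "pairwise_branch_difference",
    "relative_branch_position",
    "spine_density",
    "compare_paired",
    "load_trial_table",
    "load_spine_summary",
    "estimates_to_frame",
]

# A trial outcome is simply an (s1, s2) pair of {0,1} flags.
TrialOutcome = tuple[int, int]


@dataclass(frozen=True)
class PairedCounts:
    """Outcome counts of a paired-pulse trial series.

    ``nAB`` counts trials with first-pulse flag A and second-pulse flag B.
    """

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        for v in (self.n00, self.n01, self.n10, self.n11):
            if v < 0 or int(v) != v:
                raise ValueError("outcome counts must be non-negative integers")

    @property
    def N(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11


@dataclass(frozen=True)
class QuantalEstimates:
    """Release-probability estimates for one synapse.

    ``P2_star``, ``PPR`` and ``PPR_star`` are ``None`` when undefined (no
    first-pulse failures, or P1 = 0): the undefinedness is surfaced, never
    silently coerced to a number.
    """

    P1: float
    P2: float
    P2_star: float | None
    PPR: float | None
    PPR_star: float | None
    N: int


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares fit of y against x with the slope t-test."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "n": self.n,
        }


# ---------------------------------------------------------------------------
# Trace classification
# ---------------------------------------------------------------------------

SMOOTH_MS = 10.0   # boxcar width for the amplitude measure


def _pulse_peak(trace, stim_ms: float, window: tuple[float, float],
                baseline_mean: float, smooth_ms: float = SMOOTH_MS) -> float:
    """Response amplitude after a stimulus: peak of the boxcar-smoothed
    signal (minus baseline mean) within the response window.

    Smoothing keeps the raw-noise maximum over the window well below the
    2-SD criterion while barely attenuating the much slower Ca2+ transient.
    """
    lo = stim_ms + window[0]
    hi = stim_ms + window[1]
    if hi > trace.time_ms[-1] + 1e-9:
        raise ValueError("response window extends past the end of the trace")
    dt = float(trace.time_ms[1] - trace.time_ms[0])
    k = max(1, int(round(smooth_ms / dt)))
    if k > 1:
        kernel = np.ones(k) / k
        sm = np.convolve(trace.values, kernel, mode="same")
    else:
        sm = trace.values
    sel = (trace.time_ms >= lo) & (trace.time_ms <= hi)
    return float(np.max(sm[sel]) - baseline_mean)


def classify_trial(trace, stim_times: Sequence[float],
                   baseline_window: tuple[float, float] | None = None,
                   k_sd: float = 2.0,
                   response_window: tuple[float, float] = (5.0, 45.0),
                   noise_sd: float | None = None,
                   threshold_offset: float = 0.0) -> TrialOutcome:
    """Score one paired-pulse trace as a success/failure pair.

    A pulse is scored 1 iff its response amplitude (smoothed peak within
    ``response_window`` after the stimulus, relative to the pre-stimulus
    baseline mean) exceeds ``threshold_offset + k_sd * SD`` — two standard
    deviations of the failure signal by default.  ``noise_sd`` defaults to
    the baseline SD of this trace; :func:`classify_trials` replaces it with
    the failure-amplitude statistics in a refinement pass.
    """
    t0 = float(stim_times[0])
    if baseline_window is None:
        baseline_window = (float(trace.time_ms[0]), t0)
    if baseline_window[1] > t0 + 1e-9:
        raise ValueError("baseline window must precede the first stimulus")
    base_sel = (trace.time_ms >= baseline_window[0]) & (trace.time_ms < baseline_window[1])
    if not np.any(base_sel):
        raise ValueError("empty baseline window")
    base = trace.values[base_sel]
    mu = float(np.mean(base))
    sd = float(np.std(base, ddof=1)) if noise_sd is None else float(noise_sd)
    flags = []
    for j, s in enumerate(stim_times):
        s = float(s)
        if j == 0:
            ref = mu
        else:
            # later pulses ride the decay of earlier responses: score their
            # amplitude against the signal level just before the stimulus
            pre = (trace.time_ms >= s - 20.0) & (trace.time_ms < s)
            ref = float(np.mean(trace.values[pre])) if np.any(pre) else mu
        amp = _pulse_peak(trace, s, response_window, ref)
        flags.append(int(amp > threshold_offset + k_sd * sd))
    return (flags[0], flags[1]) if len(flags) == 2 else tuple(flags)  # type: ignore[return-value]


def classify_trials(traces: Sequence, stim_times: Sequence[float],
                    k_sd: float = 2.0,
                    response_window: tuple[float, float] = (5.0, 45.0),
                    ) -> list[TrialOutcome]:
    """Classify a trial ensemble with one failure-SD refinement pass.

    First pass: each trace is scored against its own baseline SD.  The
    response-amplitude distribution of first-pulse failure trials — the
    signal during release failures — is then characterised (mean, SD) and
    every trace is re-scored once against mean + k_sd·SD of that
    distribution.  One pass keeps the procedure deterministic.
    """
    first = [classify_trial(tr, stim_times, k_sd=k_sd,
                            response_window=response_window) for tr in traces]
    fail_samples = []
    for tr, out in zip(traces, first):
        if out[0] == 0:
            t0 = float(stim_times[0])
            base_sel = trace_baseline_mask(tr, t0)
            mu = float(np.mean(tr.values[base_sel]))
            win = ((tr.time_ms >= t0 + response_window[0])
                   & (tr.time_ms <= t0 + response_window[1]))
            fail_samples.append(tr.values[win] - mu)
    if len(fail_samples) < 3:  # too few failures to re-estimate; keep pass 1
        return first
    # pooled per-sample SD of the signal during release failures
    sd_fail = float(np.std(np.concatenate(fail_samples), ddof=1))
    return [classify_trial(tr, stim_times, k_sd=k_sd,
                           response_window=response_window, noise_sd=sd_fail)
            for tr in traces]


def trace_baseline_mask(trace, t0: float) -> np.ndarray:
    return (trace.time_ms >= trace.time_ms[0]) & (trace.time_ms < t0)


# ---------------------------------------------------------------------------
# Counting and estimation
# ---------------------------------------------------------------------------

def count_outcomes(outcomes: Iterable[TrialOutcome]) -> PairedCounts:
    """Tally (s1, s2) outcome pairs into the four paired counts."""
    n = {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 0}
    total = 0
    for s1, s2 in outcomes:
        if s1 not in (0, 1) or s2 not in (0, 1):
            raise ValueError(f"outcome flags must be 0/1, got {(s1, s2)}")
        n[(int(s1), int(s2))] += 1
        total += 1
    if total == 0:
        raise ValueError("cannot count an empty outcome sequence")
    return PairedCounts(n00=n[(0, 0)], n01=n[(0, 1)], n10=n[(1, 0)], n11=n[(1, 1)])


def estimate_release(counts: PairedCounts) -> QuantalEstimates:
    """Compute P1, P2, P2*, PPR and PPR* from paired outcome counts."""
    N = counts.N
    if N < 1:
        raise ValueError("need at least one trial")
    P1 = (counts.n10 + counts.n11) / N
    P2 = (counts.n01 + counts.n11) / N
    n_fail1 = counts.n00 + counts.n01
    P2_star = counts.n01 / n_fail1 if n_fail1 > 0 else None
    PPR = P2 / P1 if P1 > 0 else None
    PPR_star = (P2_star / P1) if (P2_star is not None and P1 > 0) else None
    return QuantalEstimates(P1=P1, P2=P2, P2_star=P2_star, PPR=PPR,
                            PPR_star=PPR_star, N=N)


# ---------------------------------------------------------------------------
# Trend statistics
# ---------------------------------------------------------------------------

def regress_trend(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS regression of y on x with the two-sided slope t-test and Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a trend regression")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression input")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            pearson_r=float(res.rvalue), p_value=float(res.pvalue),
                            n=len(x))


def bin_and_pool(x: Sequence[float], y: Sequence[float], bin_width: float = 25.0,
                 ) -> tuple[pd.DataFrame, RegressionResult]:
    """Pool y over distance bins and regress on the bin means.

    Averaging over 25 µm distance bins cancels the symmetric per-synapse
    scatter and raises Pearson's r without changing the underlying trend.
    Empty bins are skipped; the regression runs on per-bin means of x and y.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    edges = np.arange(np.floor(x.min() / bin_width) * bin_width,
                      x.max() + bin_width, bin_width)
    idx = np.digitize(x, edges[1:-1], right=False)
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        rows.append({"bin_centre": float(edges[b] + bin_width / 2),
                     "x_mean": float(x[sel].mean()),
                     "y_mean": float(y[sel].mean()),
                     "n": int(sel.sum())})
    binned = pd.DataFrame(rows)
    if len(binned) < 2:
        raise ValueError("need at least 2 non-empty bins")
    if len(binned) == 2:
        # regression t-test needs >= 3 points; report slope/r without a p-value
        reg = _two_point_result(binned)
    else:
        reg = regress_trend(binned["x_mean"], binned["y_mean"])
    return binned, reg


def _two_point_result(binned: pd.DataFrame) -> RegressionResult:
    dx = binned["x_mean"].iloc[1] - binned["x_mean"].iloc[0]
    dy = binned["y_mean"].iloc[1] - binned["y_mean"].iloc[0]
    return RegressionResult(slope=float(dy / dx),
                            intercept=float(binned["y_mean"].iloc[0] - dy / dx * binned["x_mean"].iloc[0]),
                            pearson_r=float(np.sign(dy / dx)) if dy != 0 else 0.0,
                            p_value=float("nan"), n=2)


def pairwise_branch_difference(
        pairs: Sequence[tuple[QuantalEstimates, QuantalEstimates, float]],
) -> tuple[pd.DataFrame, RegressionResult]:
    """Percentage Pr difference between same-branch synapse pairs vs separation.

    %ΔPr = 100·|P1_a − P1_b| / mean(P1_a, P1_b); the pair mean is a symmetric
    reference.  Regression of %ΔPr against along-branch separation tests
    whether similar-fidelity synapses group together (positive slope: nearby
    pairs more alike).
    """
    rows = []
    for a, b, sep in pairs:
        if sep <= 0:
            raise ValueError("pair separation must be positive")
        m = (a.P1 + b.P1) / 2
        if m == 0:
            raise ValueError("both P1 are zero; percentage difference undefined")
        rows.append({"separation_um": float(sep),
                     "pct_delta_pr": 100.0 * abs(a.P1 - b.P1) / m})
    df = pd.DataFrame(rows)
    reg = regress_trend(df["separation_um"], df["pct_delta_pr"])
    return df, reg


def relative_branch_position(distance_branch_origin: float, branch_length: float) -> float:
    """Scale a synapse coordinate to [0, 1] between branch origin and end."""
    if branch_length <= 0:
        raise ValueError("branch length must be positive")
    if not 0 <= distance_branch_origin <= branch_length:
        raise ValueError("distance must lie within the branch")
    return distance_branch_origin / branch_length


def spine_density(positions: Sequence[float], centre: float, window: float = 10.0) -> int:
    """Count spines within a closed window centred on a synapse.

    The density readout is the number of visible protrusions along a
    ``window`` µm (default 10 µm) stretch of dendrite centred on the synapse;
    both window edges are inclusive.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        return 0
    lo, hi = centre - window / 2, centre + window / 2
    return int(np.sum((pos >= lo) & (pos <= hi)))


def compare_paired(a: Sequence[float], b: Sequence[float], test: str = "t") -> float:
    """Two-sided paired comparison; ``test`` selects t-test or Wilcoxon.

    Test selection is a caller decision (normality checks are not automated).
    Identical samples return p = 1.0 (the degenerate zero-variance case).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 5:
        raise ValueError("need n >= 5 for a paired comparison")
    d = a - b
    if np.all(d == 0):
        if test == "wilcoxon":
            raise ValueError("all-zero differences: Wilcoxon test undefined")
        return 1.0
    if test == "t":
        return float(stats.ttest_rel(a, b).pvalue)
    if test == "wilcoxon":
        return float(stats.wilcoxon(a, b).pvalue)
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def load_trial_table(path) -> pd.DataFrame:
    """Read a per-trial CSV (spine_id, distance_um, ..., trial_idx, s1, s2)."""
    df = pd.read_csv(path)
    required = {"spine_id", "distance_um", "trial_idx", "s1", "s2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df


def load_spine_summary(path) -> pd.DataFrame:
    """Read a per-spine summary CSV (spine_id, distance_um, P1[, P2, PPR]).

    Matches the layout of published per-synapse readout tables so externally
    provided summary spreadsheets (exported to CSV) can be analysed directly.
    """
    df = pd.read_csv(path)
    required = {"spine_id", "distance_um", "P1"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spine summary missing columns: {sorted(missing)}")
    return df


def estimates_to_frame(records: Sequence[tuple[str, float, QuantalEstimates]]) -> pd.DataFrame:
    """Tidy per-spine estimate table from (spine_id, distance_um, estimates)."""
    rows = []
    for spine_id, dist, est in records:
        rows.append({"spine_id": spine_id, "distance_um": dist, "P1": est.P1,
                     "P2": est.P2, "P2_star": est.P2_star, "PPR": est.PPR,
                     "PPR_star": est.PPR_star, "N": est.N})
    return pd.DataFrame(rows)


def analyse_trial_table(df: pd.DataFrame, bin_width: float = 25.0) -> dict:
    """Full OQA report for a per-trial table: estimates plus trend statistics."""
    records = []
    for spine_id, g in df.groupby("spine_id", sort=False):
        g = g.sort_values("trial_idx")
        est = estimate_release(count_outcomes(list(zip(g["s1"], g["s2"]))))
        records.append((spine_id, float(g["distance_um"].iloc[0]), est))
    table = estimates_to_frame(records)
    report: dict = {"n_spines": len(table),
                    "mean_P1": float(table["P1"].mean())}
    reg = regress_trend(table["distance_um"], table["P1"])
    report["p1_vs_distance"] = reg.as_dict()
    _, breg = bin_and_pool(table["distance_um"], table["P1"], bin_width)
    report["p1_vs_distance_binned"] = breg.as_dict()
    ppr = table.dropna(subset=["PPR"])
    if len(ppr) >= 3:
        report["mean_PPR"] = float(ppr["PPR"].mean())
        report["ppr_vs_distance"] = regress_trend(ppr["distance_um"], ppr["PPR"]).as_dict()
    pps = table.dropna(subset=["PPR_star"])
    if len(pps) >= 3:
        report["mean_PPR_star"] = float(pps["PPR_star"].mean())
    return {"table": table, "report": report}


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
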