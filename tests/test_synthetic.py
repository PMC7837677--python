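"""Tests for the synthetic-data generators (trial tables, traces, morphology)."""

import math

import numpy as np
import pytest

from synaptrend.morphology import Morphology
from synaptrend.quantal import classify_trial, classify_trials, count_outcomes, estimate_release
from synaptrend.synthetic import (NoiseModel, SpilloverConfig,
                                  generate_iglu_dataset, generate_linescan_trace,
                                  generate_linescan_trials, generate_morphology,
                                  generate_spine_dataset, sphere_volume,
                                  spine_dataset_to_frame)


class TestSpillover:
    def test_sphere_volume_at_2um(self):
        # 4/3 pi 8 = 33.5 µm³, i.e. ~33 truncated
        assert math.floor(sphere_volume(2.0)) == 33

    def test_neighbour_count_exceeds_60(self):
        sc = SpilloverConfig(synapse_density=2.0, detection_radius=2.0)
        assert sc.n_neighbours == math.floor(2.0 * sphere_volume(2.0))
        assert sc.n_neighbours > 60

    def test_validation(self):
        with pytest.raises(ValueError):
            SpilloverConfig(activated_fraction=0.0)


class TestSpineDataset:
    def test_trend_formula_ground_truth(self):
        # spine at x has true_P1 = 0.18 + 0.0012 x exactly (within clipping)
        data = generate_spine_dataset(n_spines=40, seed=1, pr_jitter_sd=0.0)
        for spine, _ in data:
            assert spine.true_P1 == pytest.approx(
                0.18 + 0.0012 * spine.distance_soma)
            ppr = 3.31 - 0.0074 * spine.distance_soma
            assert spine.true_P2 == pytest.approx(
                min(0.99, spine.true_P1 * ppr))

    def test_degenerate_probability_one(self):
        data = generate_spine_dataset(n_spines=3, trials_per_spine=20,
                                      trend_slope=0.0, trend_intercept=1.0,
                                      pr_jitter_sd=0.0, seed=0)
        for _, trials in data:
            assert all(s1 == 1 for s1, _ in trials)

    def test_empirical_p1_matches_binomial_oracle(self):
        """Mean of per-spine P-hat-1 is within 3 SEM of the ground-truth mean."""
        data = generate_spine_dataset(n_spines=67, trials_per_spine=20, seed=3)
        true = np.array([s.true_P1 for s, _ in data])
        est = np.array([np.mean([t[0] for t in trials]) for _, trials in data])
        sem = np.sqrt(np.mean(true * (1 - true) / 20) / 67)
        assert abs(est.mean() - true.mean()) <= 3 * sem

    def test_per_spine_frequency_converges(self):
        """|P-hat - P| <= 3 sqrt(P(1-P)/N) for nearly all spines/seeds."""
        ok = tot = 0
        for seed in range(20):
            data = generate_spine_dataset(n_spines=30, trials_per_spine=25,
                                          seed=seed)
            for spine, trials in data:
                phat = np.mean([t[0] for t in trials])
                tol = 3 * math.sqrt(spine.true_P1 * (1 - spine.true_P1) / 25)
                ok += abs(phat - spine.true_P1) <= tol
                tot += 1
        assert ok / tot >= 0.99

    def test_reproducible(self):
        a = spine_dataset_to_frame(generate_spine_dataset(n_spines=10, seed=9))
        b = spine_dataset_to_frame(generate_spine_dataset(n_spines=10, seed=9))
        assert a.equals(b)

    def test_validation(self):
        with pytest.raises(ValueError):
            generate_spine_dataset(n_spines=0)
        with pytest.raises(ValueError):
            generate_spine_dataset(distance_range=(350.0, 40.0))

    def test_independent_pulses_make_p2star_match_p2(self):
        """Under independent second-pulse draws, E[P2*] = E[P2]."""
        p2s, p2 = [], []
        for seed in range(40):
            data = generate_spine_dataset(n_spines=20, trials_per_spine=30,
                                          seed=100 + seed)
            for _, trials in data:
                e = estimate_release(count_outcomes(trials))
                if e.P2_star is not None:
                    p2s.append(e.P2_star)
                    p2.append(e.P2)
        assert np.mean(p2s) == pytest.approx(np.mean(p2), abs=0.02)


class TestLinescanTraces:
    def test_noiseless_single_transient(self):
        noise = NoiseModel(baseline_sd=0.0, success_amplitude_mean=10.0,
                           success_amplitude_cv=0.0, seed=0)
        tr = generate_linescan_trace((1, 0), noise)
        # one transient, sampled peak within half a percent of the amplitude
        assert tr.values.max() == pytest.approx(10.0, rel=5e-3)
        after_second = tr.time_ms >= tr.stim_times[1]
        assert tr.values[after_second].max() < tr.values.max()

    def test_failure_trace_stays_in_noise(self):
        """(0,0) traces rarely produce 3-SD response amplitudes."""
        from synaptrend.quantal import _pulse_peak
        hits = 0
        for seed in range(40):
            tr = generate_linescan_trace((0, 0), NoiseModel(seed=seed))
            base = tr.values[tr.time_ms < tr.stim_times[0]]
            amp = _pulse_peak(tr, tr.stim_times[0], (5.0, 45.0), base.mean())
            hits += amp > 3 * base.std(ddof=1)
        assert hits <= 2

    def test_classifier_round_trip_high_snr(self):
        """Classifier recovers ground truth on >= 99% of 8-SD trials."""
        rng = np.random.default_rng(5)
        outcomes = [tuple(rng.integers(0, 2, 2)) for _ in range(250)]
        noise = NoiseModel(baseline_sd=1.0, success_amplitude_mean=8.0,
                           success_amplitude_cv=0.2, seed=11)
        traces = generate_linescan_trials(outcomes, noise)
        got = classify_trials(traces, traces[0].stim_times)
        agree = np.mean([g == o for g, o in zip(got, outcomes)])
        assert agree >= 0.99

    def test_stimulus_outside_window_rejected(self):
        with pytest.raises(ValueError):
            generate_linescan_trace((1, 1), NoiseModel(), stim_times=(400.0, 600.0))


class TestIgluDataset:
    def test_no_failures_with_spillover(self):
        """With >60 neighbours at P=0.36, all-failure pulses are impossible
        in practice ((1-0.36)^60 < 1e-11): every trace shows a response."""
        traces = generate_iglu_dataset(n_boutons=20, seed=2, noise_sd=0.0)
        for tr in traces:
            t0 = tr.stim_times[0]
            f0 = tr.values[tr.time_ms < t0].mean()
            peak = tr.values[(tr.time_ms >= t0) & (tr.time_ms < t0 + 50)].max()
            assert peak > f0 * 1.01   # >1% dF/F response on pulse 1

    def test_single_synapse_failure_rate(self):
        """With one active synapse, ~half of first pulses fail at P=0.5."""
        spill = SpilloverConfig(synapse_density=2.0, activated_fraction=1 / 67)
        fails = 0
        n = 150
        traces = generate_iglu_dataset(n_boutons=n, spill=spill, seed=7,
                                       base_p1=0.5, noise_sd=0.0)
        for tr in traces:
            t0 = tr.stim_times[0]
            f0 = tr.values[tr.time_ms < t0].mean()
            peak = tr.values[(tr.time_ms >= t0) & (tr.time_ms < t0 + 40)].max()
            fails += peak <= f0 * (1 + 1e-9)
        assert 0.35 <= fails / n <= 0.65

    def test_mean_ppr_matches_observed_scale(self):
        """The default PPR profile averages near the observed 1.49."""
        traces = generate_iglu_dataset(n_boutons=300, seed=3)
        mean_ppr = np.mean([tr.meta["true_ppr"] for tr in traces])
        assert mean_ppr == pytest.approx(1.49, abs=0.05)

    def test_frame_subsampling(self):
        traces = generate_iglu_dataset(n_boutons=2, mode="frame_subsampled", seed=1)
        dt = np.diff(traces[0].time_ms)
        assert np.allclose(dt, 20.0)
        assert len(traces[0].stim_times) == 5

    def test_zero_neighbours_rejected(self):
        spill = SpilloverConfig(synapse_density=2.0, activated_fraction=1e-6)
        with pytest.raises(ValueError):
            generate_iglu_dataset(n_boutons=2, spill=spill)


class TestMorphologyGenerator:
    def test_ball_and_stick_path_distance(self):
        m = generate_morphology(n_obliques=0, n_basal=0, trunk_length=400.0)
        assert m.path_distance().max() == pytest.approx(400.0)

    def test_swc_round_trip(self, tmp_path):
        m = generate_morphology(seed=4)
        p = tmp_path / "cell.swc"
        m.to_swc(p)
        m2 = Morphology.from_swc(p)
        assert m2.n_nodes == m.n_nodes
        assert np.array_equal(m2.parent, m.parent)
        assert np.allclose(m2.xyz, m.xyz, atol=1e-3)
        assert np.allclose(m2.radius, m.radius, atol=1e-3)

    def test_path_distance_monotone_to_tips(self):
        m = generate_morphology(seed=8)
        d = m.path_distance()
        for i in range(1, m.n_nodes):
            assert d[i] > d[m.parent[i]]

    def test_invalid_diameters(self):
        with pytest.raises(ValueError):
            generate_morphology(diameters={"oblique": -1.0})
        with pytest.raises(ValueError):
            generate_morphology(trunk_length=200.0)

    def test_oblique_coverage_of_placement_range(self):
        """Thin (oblique) compartments span every distance in 40-350 µm."""
        from synaptrend.cable import discretise
        c = discretise(generate_morphology(), 10.0)
        for x in np.linspace(40, 350, 32):
            cands = c.comp_at_distance(float(x))
            assert np.any(c.radius_um[cands] <= 0.55)
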