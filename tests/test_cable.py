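"""Cable-solver tests: discretisation geometry, analytic oracles, convergence,
EPSP measurement and spike detection."""

import math

import numpy as np
import pytest

from synaptrend.cable import (ActiveParams, CableParams, ConductanceEvent,
                              VoltageTrace, detect_spikes, discretise,
                              epsp_amplitude, exp2syn_peak_factor, simulate)
from synaptrend.synthetic import generate_morphology

from conftest import cylinder_morphology


class TestDiscretise:
    def test_cylinder_segment_count(self):
        comps = discretise(cylinder_morphology(100.0, node_um=50.0), 10.0)
        assert comps.n == 10
        assert np.allclose(comps.length_um, 10.0)

    def test_area_matches_analytic_frustum(self):
        """Summed compartment areas equal the analytic frustum area."""
        from synaptrend.morphology import Morphology
        m = Morphology(xyz=np.array([[0, 0, 0], [0, 120.0, 0]]),
                       radius=np.array([2.0, 0.5]),
                       parent=np.array([-1, 0]), ntype=np.array([4, 4]))
        comps = discretise(m, 7.0)
        slant = math.sqrt(120.0 ** 2 + 1.5 ** 2) * 1e-4
        analytic = math.pi * 2.5 * 1e-4 * slant
        assert comps.area_cm2.sum() == pytest.approx(analytic, rel=1e-12)

    def test_refinement_changes_steady_state_little(self):
        """10 µm -> 5 µm refinement moves the steady soma voltage < 1%."""
        m = generate_morphology(n_obliques=4, oblique_spacing=60.0,
                                n_basal=2, basal_length=100.0)
        params = CableParams()
        vals = []
        for seg in (10.0, 5.0):
            comps = discretise(m, seg)
            tr = simulate(comps, params, [], duration_ms=200.0,
                          stabilise_ms=100.0, iclamp=[(comps.n - 1, 0.02)])
            vals.append(tr.v_final[0] - params.E_leak)
        assert abs(vals[1] / vals[0] - 1) < 0.01

    def test_parent_ordering_invariant(self, default_comps):
        assert np.all(default_comps.parent[1:] < np.arange(1, default_comps.n))

    def test_invalid_seg_len(self):
        with pytest.raises(ValueError):
            discretise(cylinder_morphology(), 0.0)


class TestCableOracles:
    def test_zero_input_voltage_conserved(self, small_comps):
        tr = simulate(small_comps, CableParams(), [], duration_ms=80.0,
                      stabilise_ms=50.0)
        assert np.max(np.abs(tr.vm_soma - CableParams().E_leak)) < 1e-3  # < 1 µV

    def test_steady_state_space_constant(self):
        """Steady attenuation along a long uniform cylinder matches
        exp(-x/lambda), lambda = sqrt(r Rm / (2 Ra)), within 2%."""
        m = cylinder_morphology(length_um=5300.0, radius_um=0.5, node_um=50.0)
        comps = discretise(m, 10.0)
        params = CableParams()
        tr = simulate(comps, params, [], duration_ms=500.0,
                      stabilise_ms=100.0, iclamp=[(0, 0.005)])
        v = tr.v_final - params.E_leak
        x = comps.path_mid_um
        lam_um = math.sqrt(0.5e-4 * 28000.0 / (2 * 90.0)) * 1e4
        sel = (x > 800) & (x < 2200)
        ratio = v[sel] / v[sel][0]
        pred = np.exp(-(x[sel] - x[sel][0]) / lam_um)
        assert np.max(np.abs(ratio / pred - 1)) < 0.02

    def test_dt_halving_epsp_convergence(self, small_comps):
        """Halving dt changes the EPSP peak by < 0.5%."""
        comp = int(small_comps.comp_at_distance(150.0)[0])
        peaks = []
        for dt in (0.025, 0.0125):
            tr = simulate(small_comps, CableParams(),
                          [ConductanceEvent(comp=comp, onset_ms=10.0, gmax_uS=0.002)],
                          duration_ms=80.0, dt=dt, stabilise_ms=100.0)
            amp, _ = epsp_amplitude(tr, 10.0, 45.0, baseline_time=0.0)
            peaks.append(amp)
        assert abs(peaks[1] / peaks[0] - 1) < 0.005

    def test_exp2syn_peak_equals_gmax(self):
        """The normalised dual-exponential conductance peaks at Gm."""
        tau1, tau2 = 1.0, 20.0
        f = exp2syn_peak_factor(tau1, tau2)
        t = np.linspace(0, 100, 20001)
        g = f * (np.exp(-t / tau2) - np.exp(-t / tau1))
        assert g.max() == pytest.approx(1.0, rel=1e-6)


class TestEpspProperties:
    def test_excitatory_event_depolarises(self, small_comps):
        """E_rev = 0 with rest below zero: every event gives EPSP in
        (0, driving force)."""
        for x in (60.0, 150.0, 280.0):
            comp = int(small_comps.comp_at_distance(x)[0])
            tr = simulate(small_comps, CableParams(),
                          [ConductanceEvent(comp=comp, onset_ms=10.0, gmax_uS=0.001)],
                          duration_ms=80.0, stabilise_ms=100.0)
            amp, _ = epsp_amplitude(tr, 10.0, 45.0, baseline_time=0.0)
            assert 0 < amp < 65.0

    def test_zero_conductance_gives_zero(self, small_comps):
        comp = int(small_comps.comp_at_distance(100.0)[0])
        tr = simulate(small_comps, CableParams(),
                      [ConductanceEvent(comp=comp, onset_ms=10.0, gmax_uS=1e-12)],
                      duration_ms=80.0, stabilise_ms=100.0)
        amp, _ = epsp_amplitude(tr, 10.0, 45.0, baseline_time=0.0)
        assert amp == pytest.approx(0.0, abs=1e-6)

    def test_summation_is_sublinear(self, small_comps):
        """Two co-located synapses sum strictly sublinearly."""
        comp = int(small_comps.comp_at_distance(150.0)[0])
        def peak(g, n):
            evs = [ConductanceEvent(comp=comp, onset_ms=10.0, gmax_uS=g)] * n
            tr = simulate(small_comps, CableParams(), evs, duration_ms=80.0,
                          stabilise_ms=100.0)
            return epsp_amplitude(tr, 10.0, 45.0, baseline_time=0.0)[0]
        one = peak(0.002, 1)
        two = peak(0.002, 2)
        assert two < 2 * one
        assert two > one

    def test_fixed_gm_epsp_decreases_with_distance(self):
        """On a thin loaded trunk, fixed-Gm EPSPs fall monotonically with
        distance, and the centrifugal Gm profile narrows the max/min spread
        (partial compensation of electrotonic attenuation)."""
        from synaptrend.synapses import gm_profile
        m = generate_morphology(
            diameters={"trunk_base": 1.2, "trunk_tip": 0.6,
                       "oblique": 0.8, "basal": 2.0},
            n_basal=6, basal_length=200.0,
            n_obliques=13, oblique_spacing=25.0, oblique_length=120.0)
        comps = discretise(m, 10.0)
        def amp(x, g):
            cands = comps.comp_at_distance(x)
            cands = cands[comps.radius_um[cands] <= 0.45]
            tr = simulate(comps, CableParams(),
                          [ConductanceEvent(comp=int(cands[0]), onset_ms=10.0,
                                            gmax_uS=g)],
                          duration_ms=80.0, stabilise_ms=100.0)
            return epsp_amplitude(tr, 10.0, 45.0, baseline_time=0.0)[0]
        xs = [60.0, 150.0, 250.0, 340.0]
        fixed = [amp(x, 0.0002) for x in xs]
        scaled = [amp(x, float(gm_profile(x, 0.0002))) for x in xs]
        assert all(a > b for a, b in zip(fixed[:-1], fixed[1:]))
        assert max(scaled) / min(scaled) < max(fixed) / min(fixed)

    def test_second_pulse_linearity_and_onset_convention(self, default_comps):
        """Passive small-signal pairs superpose linearly (solver check); the
        onset-subtraction convention reads the second amplitude low by the
        decay of the first response over the second peak's latency — a known,
        bounded measurement bias, not a physical depression."""
        params = CableParams(spine_area_scale=3.0)
        comp = int(default_comps.comp_at_distance(100.0)[0])
        e1 = ConductanceEvent(comp=comp, onset_ms=10.0, gmax_uS=0.0005)
        e2 = ConductanceEvent(comp=comp, onset_ms=60.0, gmax_uS=0.0005)
        pair = simulate(default_comps, params, [e1, e2], duration_ms=160.0,
                        stabilise_ms=100.0)
        one = simulate(default_comps, params, [e1], duration_ms=160.0,
                       stabilise_ms=100.0)
        two = simulate(default_comps, params, [e2], duration_ms=160.0,
                       stabilise_ms=100.0)
        superposed = one.vm_soma + two.vm_soma - params.E_leak
        a1, _ = epsp_amplitude(pair, 10.0, 45.0, baseline_time=0.0)
        assert np.max(np.abs(pair.vm_soma - superposed)) < 0.01 * a1
        a2, _ = epsp_amplitude(pair, 60.0, 45.0)
        assert 0.6 * a1 < a2 <= 1.02 * a1


class TestSpikes:
    def test_subthreshold_trace_empty(self):
        t = np.arange(0, 100.0, 0.1)
        tr = VoltageTrace(time_ms=t, vm_soma=np.full_like(t, -60.0), dt_ms=0.1)
        assert len(detect_spikes(tr)) == 0

    def test_three_spike_waveform(self):
        t = np.arange(0, 100.0, 0.1)
        v = np.full_like(t, -65.0)
        for t0 in (20.0, 50.0, 80.0):
            v += 100.0 * np.exp(-0.5 * ((t - t0) / 0.4) ** 2)
        tr = VoltageTrace(time_ms=t, vm_soma=v, dt_ms=0.1)
        assert len(detect_spikes(tr)) == 3

    def test_count_invariant_to_threshold(self):
        t = np.arange(0, 100.0, 0.1)
        v = np.full_like(t, -65.0)
        for t0 in (30.0, 70.0):
            v += 105.0 * np.exp(-0.5 * ((t - t0) / 0.4) ** 2)
        tr = VoltageTrace(time_ms=t, vm_soma=v, dt_ms=0.1)
        for thr in (-10.0, -5.0, 0.0, 5.0, 10.0):
            assert len(detect_spikes(tr, threshold=thr)) == 2

    def test_hh_soma_fires_on_strong_input(self, small_comps):
        """Strong synchronous drive at spiking scale elicits somatic spikes
        crossing 0 mV."""
        comps = small_comps
        events = []
        for x in (60.0, 100.0, 150.0, 200.0, 250.0):
            for c in comps.comp_at_distance(x)[:2]:
                events.append(ConductanceEvent(comp=int(c), onset_ms=10.0,
                                               gmax_uS=0.06))
        tr = simulate(comps, CableParams(active=ActiveParams()), events,
                      duration_ms=60.0, stabilise_ms=200.0)
        assert len(detect_spikes(tr)) >= 1


class TestValidation:
    def test_event_kinetics_must_match(self, small_comps):
        evs = [ConductanceEvent(comp=1, onset_ms=5.0, gmax_uS=0.001, tau2=20.0),
               ConductanceEvent(comp=1, onset_ms=6.0, gmax_uS=0.001, tau2=30.0)]
        with pytest.raises(ValueError):
            simulate(small_comps, CableParams(), evs, duration_ms=50.0)

    def test_dt_vs_rise_time(self, small_comps):
        ev = [ConductanceEvent(comp=1, onset_ms=5.0, gmax_uS=0.001, tau1=0.05)]
        with pytest.raises(ValueError):
            simulate(small_comps, CableParams(), ev, duration_ms=50.0, dt=0.025)

    def test_event_outside_window(self, small_comps):
        ev = [ConductanceEvent(comp=1, onset_ms=500.0, gmax_uS=0.001)]
        with pytest.raises(ValueError):
            simulate(small_comps, CableParams(), ev, duration_ms=50.0)

    def test_bad_event_taus(self):
        with pytest.raises(ValueError):
            ConductanceEvent(comp=0, onset_ms=0.0, gmax_uS=0.001,
                             tau1=20.0, tau2=1.0)
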