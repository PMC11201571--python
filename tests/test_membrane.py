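import math

import numpy as np
import pandas as pd
import pytest

from wormbot.connectome import ChannelGeneMap, GeneExpressionTable
from wormbot.membrane import (
    CELEGANS_CONSTANTS,
    MembraneState,
    NeuronParams,
    StimulusProtocol,
    VoltageTrace,
    channel_currents,
    classical_squid_params,
    classify_response,
    conductances_from_expression,
    detect_spikes,
    find_critical_leak,
    gating_rates,
    resting_state,
    simulate_neuron,
    steady_state_gates,
)

VGRID = np.linspace(-120.0, 60.0, 361)


class TestGatingRates:
    def test_rates_finite_at_removable_singularities(self):
        for v in (-40.0, -55.0, -40.0 + 1e-9, -55.0 - 1e-9):
            rates = gating_rates(v)
            for a, b in rates.values():
                assert math.isfinite(a) and math.isfinite(b)
        # the limit values connect continuously
        am_limit = gating_rates(-40.0)["m"][0]
        am_near = gating_rates(-40.0 + 1e-5)["m"][0]
        assert am_limit == pytest.approx(am_near, rel=1e-4)

    def test_rates_nonnegative_on_grid(self):
        for v in VGRID:
            for a, b in gating_rates(v).values():
                assert a >= 0.0 and b >= 0.0

    def test_steady_states_in_unit_interval_and_monotone(self):
        table = {g: [] for g in ("m", "n", "h", "mca", "hca")}
        for v in VGRID:
            for gate, x in steady_state_gates(v).items():
                assert 0.0 <= x <= 1.0
                table[gate].append(x)
        for gate in ("m", "n", "mca"):  # activation gates open with V
            assert np.all(np.diff(table[gate]) >= -1e-12), gate
        for gate in ("h", "hca"):  # inactivation gates close with V
            assert np.all(np.diff(table[gate]) <= 1e-12), gate


class TestChannelCurrents:
    def test_reversal_potentials_zero_their_currents(self):
        p = CELEGANS_CONSTANTS
        s = MembraneState(V=p.VK, m=0.5, n=0.7, h=0.5, mca=0.3, hca=0.8)
        assert channel_currents(s, p)["IK"] == 0.0
        s = MembraneState(V=-84.0, m=0.5, n=0.7, h=0.5)
        assert channel_currents(s, p)["Il"] == 0.0  # Vl = -84 mV

    def test_closed_gates_zero_their_currents(self):
        p = NeuronParams(gCa=1.0)
        s = MembraneState(V=-20.0, m=0.9, n=0.0, h=0.0, mca=0.5, hca=0.0)
        cur = channel_currents(s, p)
        assert cur["IK"] == 0.0 and cur["INa"] == 0.0 and cur["ICa"] == 0.0

    def test_current_formulas_exact(self):
        p = NeuronParams(gK=36.0, gNa=120.0, gCa=2.0)
        s = MembraneState(V=-20.0, m=0.4, n=0.5, h=0.6, mca=0.3, hca=0.7)
        cur = channel_currents(s, p)
        assert cur["IK"] == pytest.approx(36.0 * 0.5**4 * (-20.0 + 75.0))
        assert cur["INa"] == pytest.approx(120.0 * 0.4**3 * 0.6 * (-20.0 - 55.0))
        assert cur["ICa"] == pytest.approx(2.0 * 0.3**2 * 0.7 * (-20.0 - 45.0))


class TestGeneScaling:
    def make_expr(self, values):
        return GeneExpressionTable(pd.DataFrame(
            values, index=["N1", "N2"], columns=["gk1", "gk2", "gna1"]))

    def test_zero_expression_zeroes_mapped_conductances(self):
        expr = self.make_expr(np.zeros((2, 3)))
        cmap = ChannelGeneMap({"K": ["gk1", "gk2"], "Na": ["gna1"]})
        params = conductances_from_expression(expr, cmap)
        assert params["N1"].gK == 0.0 and params["N1"].gNa == 0.0
        # unmapped channels keep the global constants
        assert params["N1"].gl == CELEGANS_CONSTANTS.gl
        assert params["N1"].Cm == CELEGANS_CONSTANTS.Cm

    def test_linearity_in_expression(self):
        base = self.make_expr([[1.0, 2.0, 0.5], [0.0, 1.0, 3.0]])
        double = self.make_expr([[2.0, 4.0, 1.0], [0.0, 2.0, 6.0]])
        cmap = ChannelGeneMap({"K": ["gk1", "gk2"], "Na": ["gna1"]})
        p1 = conductances_from_expression(base, cmap)
        p2 = conductances_from_expression(double, cmap)
        for n in ("N1", "N2"):
            assert p2[n].gK == pytest.approx(2.0 * p1[n].gK)
            assert p2[n].gNa == pytest.approx(2.0 * p1[n].gNa)

    def test_unit_conductance_arithmetic(self):
        expr = GeneExpressionTable(
            pd.DataFrame([[2.0]], index=["N1"], columns=["gk1"]))
        cmap = ChannelGeneMap({"K": ["gk1"]})
        params = conductances_from_expression(
            expr, cmap, unit_conductance={"K": 18.0})
        assert params["N1"].gK == pytest.approx(36.0)


class TestSimulateNeuron:
    def test_zero_stimulus_holds_resting_state(self):
        trace = simulate_neuron(CELEGANS_CONSTANTS, None, dt=0.01, T=500.0,
                                record_stride=10)
        v = trace.single()
        assert np.max(np.abs(v - v[0])) < 1.0

    def test_suprathreshold_low_leak_fires_periodically(self, squid):
        # below the critical leak the response is sustained and periodic
        trace = simulate_neuron(
            squid, StimulusProtocol("n", 10.0, 0.0, 500.0), dt=0.01, T=500.0,
            record_stride=10)
        cls = classify_response(trace, window=(250.0, 500.0))
        assert cls.kind == "oscillation"
        assert len(cls.spike_times) >= 10

    def test_step_halving_convergence_subthreshold(self):
        # pointwise tolerances are meaningful on smooth trajectories
        prot = StimulusProtocol("n", 2.0, 0.0, 100.0)
        coarse = simulate_neuron(CELEGANS_CONSTANTS, prot, dt=0.02, T=100.0,
                                 record_stride=5)
        fine = simulate_neuron(CELEGANS_CONSTANTS, prot, dt=0.01, T=100.0,
                               record_stride=10)
        assert np.allclose(coarse.times, fine.times)
        assert np.max(np.abs(coarse.single() - fine.single())) < 0.5

    def test_step_halving_convergence_after_spike(self, squid):
        # once the stimulus ends and the neuron has returned to rest, the
        # final voltage converges under step halving
        prot = StimulusProtocol("n", 10.0, 0.0, 30.0)
        coarse = simulate_neuron(squid, prot, dt=0.01, T=80.0, record_stride=10)
        fine = simulate_neuron(squid, prot, dt=0.005, T=80.0, record_stride=20)
        assert abs(coarse.single()[-1] - fine.single()[-1]) < 0.1

    def test_step_halving_preserves_spike_timing(self, squid):
        # on spiking trajectories the honest convergence metric is timing
        prot = StimulusProtocol("n", 10.0, 0.0, 100.0)
        coarse = simulate_neuron(squid, prot, dt=0.01, T=100.0)
        fine = simulate_neuron(squid, prot, dt=0.005, T=100.0)
        sc = detect_spikes(coarse)
        sf = detect_spikes(fine)
        assert len(sc) == len(sf)
        assert np.max(np.abs(np.array(sc) - np.array(sf))) < 0.5  # ms

    def test_trace_covers_requested_span(self):
        trace = simulate_neuron(CELEGANS_CONSTANTS, None, dt=0.01, T=50.0,
                                record_stride=100)
        assert trace.times[0] == 0.0
        assert trace.times[-1] == pytest.approx(50.0)


class TestSpikeDetection:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0.0, 100.0, 0.1)
        assert detect_spikes(np.full_like(t, -70.0), t) == []

    def test_sinusoid_crossing_count_and_spacing(self):
        t = np.arange(0.0, 100.0, 0.01)
        v = 40.0 * np.sin(2 * np.pi * t / 20.0) - 20.0
        spikes = detect_spikes(v, t, crossing=0.0, refractory=2.0)
        assert len(spikes) == 5
        assert np.allclose(np.diff(spikes), 20.0, atol=0.02)

    def test_refractory_merges_nearby_crossings(self):
        t = np.arange(0.0, 10.0, 0.1)
        v = np.full_like(t, -70.0)
        v[(t > 1.0) & (t < 1.3)] = 10.0  # first crossing
        v[(t > 2.0) & (t < 2.3)] = 10.0  # 1 ms later: inside refractory
        assert len(detect_spikes(v, t, refractory=5.0)) == 1
        assert len(detect_spikes(v, t, refractory=0.5)) == 2


class TestClassification:
    def trace_with_spikes(self, spike_times, T=200.0):
        t = np.arange(0.0, T, 0.05)
        v = np.full_like(t, -70.0)
        for s in spike_times:
            v[(t >= s) & (t < s + 1.0)] = 20.0
        return VoltageTrace(t, {"x": v})

    def test_silent_and_single(self):
        assert classify_response(self.trace_with_spikes([])).kind == "silent"
        assert classify_response(self.trace_with_spikes([50.0])).kind == "single_spike"
        assert classify_response(
            self.trace_with_spikes([50.0, 120.0])).kind == "single_spike"

    def test_regular_train_is_oscillation_with_frequency(self):
        cls = classify_response(
            self.trace_with_spikes([20.0, 40.0, 60.0, 80.0, 100.0, 120.0]))
        assert cls.kind == "oscillation"
        assert cls.frequency == pytest.approx(50.0, rel=1e-3)  # 20 ms ISI

    def test_irregular_train_is_burst(self):
        cls = classify_response(self.trace_with_spikes([20.0, 25.0, 90.0, 160.0]))
        assert cls.kind == "single_spike"
        assert cls.burst


class TestCriticalLeak:
    def test_high_leak_is_not_oscillatory(self, squid):
        from dataclasses import replace

        from wormbot.membrane import _sustained_oscillation

        assert not _sustained_oscillation(
            replace(squid, gl=1.0), amplitude=6.25, dt=0.01, T=500.0)
        assert _sustained_oscillation(
            replace(squid, gl=0.25), amplitude=6.25, dt=0.01, T=500.0)

    def test_bisection_terminates_within_tolerance(self, squid):
        # coarse dt keeps this check fast; the precise value is covered by
        # the acceptance suite
        gl = find_critical_leak(squid, bracket=(0.25, 0.35), tol=1e-3,
                                dt=0.02, T=400.0)
        assert 0.25 < gl < 0.35
        gl2 = find_critical_leak(squid, bracket=(0.25, 0.35), tol=1e-3,
                                 dt=0.02, T=400.0)
        assert gl == gl2  # deterministic

    def test_non_straddling_bracket_raises(self, squid):
        with pytest.raises(ValueError, match="bracket"):
            find_critical_leak(squid, bracket=(0.8, 1.0), dt=0.02, T=300.0)


def test_frequency_increases_with_stimulus_in_oscillation_regime(squid):
    freqs = []
    for amp in (10.0, 20.0, 30.0, 40.0, 50.0):
        trace = simulate_neuron(
            squid, StimulusProtocol("n", amp, 0.0, 400.0), dt=0.01, T=400.0,
            record_stride=10)
        cls = classify_response(trace, window=(100.0, 400.0))
        assert cls.kind == "oscillation"
        freqs.append(cls.frequency)
    assert all(b >= a for a, b in zip(freqs, freqs[1:]))


def test_invalid_membrane_state_rejected():
    with pytest.raises(ValueError):
        MembraneState(V=-65.0, m=1.5, n=0.0, h=0.0)
    with pytest.raises(ValueError):
        NeuronParams(Cm=0.0)
    with pytest.raises(ValueError):
        NeuronParams(gK=-1.0)
    with pytest.raises(ValueError):
        StimulusProtocol("x", 1.0, t_on=5.0, t_off=5.0)


def test_resting_state_is_a_fixed_point():
    from wormbot.membrane import _steady_current, resting_potential

    for params in (CELEGANS_CONSTANTS, classical_squid_params()):
        v0 = resting_potential(params)
        # zero net ionic current at rest, gates at steady state there
        assert abs(_steady_current(v0, params)) < 1e-6
        s = resting_state(params)
        x = steady_state_gates(v0, params)
        assert s.V == pytest.approx(v0)
        assert s.m == pytest.approx(x["m"])
        assert s.hca == pytest.approx(x["hca"])
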