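"""Unit tests for the modified Morris-Lecar neuron model."""

import math

import numpy as np
import pytest

from sdhspike import (NeuronParameters, StimulusProtocol, StateVector,
                      steady_state, time_constants, derivatives,
                      resting_state, simulate, save_trace, load_trace,
                      detect_spikes, classify, sweep_spike_stats)
from sdhspike.classify import classify_stats
from tests.conftest import CANONICAL_SETTINGS

P = NeuronParameters()


class TestSteadyState:
    @pytest.mark.parametrize("V,which,expected", [
        (-1.2, 0, 0.5),    # V = beta_m -> m_inf = 0.5
        (-10.0, 1, 0.5),   # V = beta_w -> w_inf = 0.5
        (-21.0, 2, 0.5),   # V = beta_z -> z_inf = 0.5
        (-60.0, 3, 0.5),   # a_inf half-activation
        (-78.0, 4, 0.5),   # b_inf half-inactivation
    ])
    def test_half_activation_points(self, V, which, expected):
        assert steady_state(V, P)[which] == pytest.approx(expected)

    def test_outputs_bounded_and_monotone(self):
        V = np.linspace(-120.0, 60.0, 500)
        m, w, z, a, b = steady_state(V, P)
        for curve in (m, w, z, a):
            assert np.all((curve > 0) & (curve < 1))
            assert np.all(np.diff(curve) > 0)  # activation increases with V
        assert np.all((b > 0) & (b < 1))
        assert np.all(np.diff(b) < 0)          # inactivation decreases with V


class TestTimeConstants:
    def test_tau_w_peak_at_half_activation(self):
        tau_w, _, _, _ = time_constants(-10.0, P)
        assert tau_w == pytest.approx(1.0)

    def test_tau_b_constant_above_minus_63(self):
        for V in (0.0, -20.0, -62.9):
            assert time_constants(V, P)[3] == pytest.approx(19.0)

    def test_tau_b_boundary_uses_formula_branch(self):
        # at exactly -63 mV the double-exponential branch applies
        expected = 1.0 / (math.exp((-63 + 46.05) / 5.0)
                          + math.exp(-(-63 + 238.4) / 37.45))
        assert time_constants(-63.0, P)[3] == pytest.approx(expected)
        assert time_constants(-63.0, P)[3] != pytest.approx(19.0)

    def test_all_positive(self):
        V = np.linspace(-120.0, 60.0, 500)
        for tau in time_constants(V, P):
            assert np.all(tau > 0)


class TestDerivatives:
    def test_zero_at_resting_fixed_point(self):
        params = NeuronParameters(gbar_Klt=3.0, gbar_KA=4.0)
        rest = resting_state(params)
        d = derivatives(rest, 0.0, params)
        for name in ("V", "w", "z", "a", "b"):
            assert abs(getattr(d, name)) < 1e-9

    def test_added_conductances_drop_out_at_zero_density(self):
        state = StateVector(V=-40.0, w=0.3, z=0.6, a=0.5, b=0.4)
        base = NeuronParameters()  # g_Klt = g_KA = 0: the starting model
        d = derivatives(state, 10.0, base)
        # manual three-conductance balance
        m = 0.5 * (1 + math.tanh((state.V - P.beta_m) / P.gamma_m))
        expected = (10.0 - P.gbar_Na * m * (state.V - P.E_Na)
                    - P.gbar_Kdr * state.w * (state.V - P.E_K)
                    - P.gbar_leak * (state.V - P.E_leak)) / P.C
        assert d.V == pytest.approx(expected)

    def test_a_current_vanishes_when_deactivated(self):
        state = StateVector(V=-40.0, w=0.3, z=0.6, a=0.0, b=0.4)
        with_A = derivatives(state, 10.0, NeuronParameters(gbar_KA=50.0))
        without = derivatives(state, 10.0, NeuronParameters(gbar_KA=0.0))
        assert with_A.V == pytest.approx(without.V)


class TestSimulate:
    @pytest.mark.parametrize("setting,expected", CANONICAL_SETTINGS)
    def test_canonical_patterns(self, setting, expected, protocol60):
        g_lt, g_a = setting
        params = NeuronParameters(gbar_Klt=g_lt, gbar_KA=g_a)
        res = simulate(params, protocol60)
        assert classify(detect_spikes(res)).name == expected

    def test_single_spike_near_onset(self, protocol60):
        res = simulate(NeuronParameters(gbar_Klt=6.0), protocol60)
        train = detect_spikes(res)
        assert train.n_spikes == 1
        assert train.spike_times[0] < 20.0

    def test_gating_bounded(self, protocol60):
        for (g_lt, g_a), _ in CANONICAL_SETTINGS:
            res = simulate(NeuronParameters(gbar_Klt=g_lt, gbar_KA=g_a), protocol60)
            for gate in (res.w, res.z, res.a, res.b):
                assert gate.min() >= 0.0 and gate.max() <= 1.0

    def test_rest_is_stable_without_stimulus(self):
        res = simulate(NeuronParameters(gbar_Klt=3.0, gbar_KA=4.0),
                       StimulusProtocol(I_stim=0.0))
        tail = res.V[res.times > res.protocol.stim_duration - 50.0]
        assert np.ptp(tail) < 1e-6

    def test_times_relative_to_onset(self, protocol60):
        res = simulate(NeuronParameters(), protocol60)
        assert res.times[0] == pytest.approx(-protocol60.settle_duration)
        assert res.times[-1] == pytest.approx(protocol60.stim_duration)
        assert np.allclose(np.diff(res.times), protocol60.dt)

    def test_trace_round_trip(self, tmp_path, protocol60):
        res = simulate(NeuronParameters(gbar_Klt=6.0), protocol60)
        path = tmp_path / "trace.csv"
        save_trace(res, path)
        back = load_trace(path)
        assert np.allclose(back.V, res.V)
        assert np.allclose(back.b, res.b)
        assert back.params == res.params
        assert back.protocol == res.protocol


class TestSweepEngine:
    def test_matches_scalar_simulation(self, protocol60):
        """The vectorized sweep and the scalar integrator are the same math."""
        settings = np.array([s for s, _ in CANONICAL_SETTINGS])
        stats = sweep_spike_stats(settings[:, 0], settings[:, 1],
                                  protocol=protocol60)
        for i, ((g_lt, g_a), _) in enumerate(CANONICAL_SETTINGS):
            res = simulate(NeuronParameters(gbar_Klt=g_lt, gbar_KA=g_a), protocol60)
            train = detect_spikes(res)
            assert stats.n_spikes[i] == train.n_spikes
            if train.n_spikes:
                assert stats.t1[i] == pytest.approx(train.spike_times[0], abs=1e-9)

    def test_dt_halving_preserves_canonical_labels(self):
        settings = np.array([s for s, _ in CANONICAL_SETTINGS])
        labels = {}
        for dt in (0.1, 0.05):
            stats = sweep_spike_stats(settings[:, 0], settings[:, 1],
                                      protocol=StimulusProtocol(I_stim=60.0, dt=dt))
            labels[dt] = classify_stats(stats)
        assert np.array_equal(labels[0.1], labels[0.05])

    def test_depolarizing_prepulse_reduces_a_current_availability(self):
        """b at stimulus onset falls monotonically with the pre-pulse."""
        b_onsets = []
        for I_pre in (0.0, 5.0, 10.0, 15.0, 20.0):
            stats = sweep_spike_stats(
                [2.0], [6.0], protocol=StimulusProtocol(I_stim=60.0, I_pre=I_pre))
            b_onsets.append(stats.b_onset[0])
        assert np.all(np.diff(b_onsets) < 0)

    def test_prepulse_raises_prestimulus_potential(self):
        stats = sweep_spike_stats([2.0, 2.0], [6.0, 6.0],
                                  protocol=StimulusProtocol(I_stim=60.0, I_pre=0.0))
        stats_dep = sweep_spike_stats([2.0], [6.0],
                                      protocol=StimulusProtocol(I_stim=60.0, I_pre=10.0))
        assert stats_dep.v_pre[0] > stats.v_pre[0]


class TestValidation:
    def test_rejects_negative_conductance(self):
        with pytest.raises(ValueError):
            NeuronParameters(gbar_KA=-1.0)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            StimulusProtocol(dt=0.0)
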