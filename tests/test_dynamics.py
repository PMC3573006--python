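"""Single-neuron dynamics: integration accuracy, synaptic currents,
conductance kinetics and the excitability feedback."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swostim.dynamics import (
    NeuronParams,
    NeuronState,
    SynapseKinetics,
    decay_conductances,
    excitability_update,
    izhikevich_step,
    nmda_gating,
    synaptic_current,
)


def integrate(params, current, duration, dt, n_substeps=2):
    """Reference integration loop returning (final state, spike count)."""
    state = NeuronState.at_rest(params)
    n_spikes = 0
    n = int(round(duration / dt))
    for i in range(n):
        state, spiked = izhikevich_step(
            state, params, current, dt, t=i * dt, n_substeps=n_substeps
        )
        state = excitability_update(state, params, dt, spiked)
        n_spikes += spiked
    return state, n_spikes


class TestIzhikevichStep:
    def test_quiescent_below_rheobase(self):
        # e_ss below the ~4 rheobase of regular-spiking parameters
        params = NeuronParams(e_ss=3.0, k_e=0.0)
        _, n = integrate(params, 0.0, 1.0, 0.5e-3)
        assert n == 0

    def test_spike_count_matches_fine_step_oracle(self):
        # suprathreshold drive: dt/10 oracle integration gives the reference
        params = NeuronParams(e_ss=0.0, k_e=0.0)
        _, n_coarse = integrate(params, 10.0, 1.0, 0.5e-3)
        _, n_fine = integrate(params, 10.0, 1.0, 0.05e-3, n_substeps=2)
        assert n_coarse > 5
        assert abs(n_coarse - n_fine) <= 1

    def test_subthreshold_linearity(self):
        # steady-state depolarization is linear in the injected current;
        # the gain z is measured with the same fine-step oracle
        params = NeuronParams(e_ss=0.0, k_e=0.0)
        dvs = []
        for current in (0.2, 0.4):
            state, n = integrate(params, current, 3.0, 0.05e-3)
            assert n == 0
            dvs.append(state.v - NeuronState.at_rest(params).v)
        z1, z2 = dvs[0] / 0.2, dvs[1] / 0.4
        assert z1 == pytest.approx(z2, rel=0.02)

    def test_rest_is_fixed_point(self):
        params = NeuronParams(e_ss=0.0, k_e=0.0)
        state, n = integrate(params, 0.0, 1.0, 0.5e-3)
        rest = NeuronState.at_rest(params)
        assert n == 0
        assert state.v == pytest.approx(rest.v, abs=1e-6)

    def test_reset_and_isi_bookkeeping(self):
        params = NeuronParams(e_ss=0.0, k_e=0.0)
        state = NeuronState.at_rest(params)
        spikes = []
        for i in range(4000):
            state, spiked = izhikevich_step(state, params, 10.0, 0.5e-3, t=i * 0.5e-3)
            if spiked:
                spikes.append(state.last_spike_time)
        assert len(spikes) >= 2
        assert state.last_isi == pytest.approx(spikes[-1] - spikes[-2])

    def test_dt_bounds(self):
        params = NeuronParams()
        with pytest.raises(ValueError):
            izhikevich_step(NeuronState(), params, 0.0, 2e-3)


class TestSynapticCurrent:
    def test_zero_conductances(self):
        assert synaptic_current(NeuronState(), SynapseKinetics()) == 0.0

    def test_reversal_potential(self):
        kin = SynapseKinetics()
        state = NeuronState(v=kin.E_exc, g_ampa=1.0, g_nmda=2.0)
        assert synaptic_current(state, kin) == 0.0

    def test_hand_computed_sum(self):
        kin = SynapseKinetics()
        v = -65.0
        state = NeuronState(v=v, g_ampa=0.5, g_nmda=0.25, g_gabaa=0.4, g_gabab=0.1)
        b = ((v + 80.0) / 60.0) ** 2 / (1.0 + ((v + 80.0) / 60.0) ** 2)
        expected = (
            0.7 * (0.5 + 0.25 * b) * (0.0 - v)
            + 0.4 * (-70.0 - v)
            + 0.1 * (-90.0 - v)
        )
        assert synaptic_current(state, kin, w_hom=0.7) == pytest.approx(expected)

    def test_w_hom_scales_excitatory_only(self):
        kin = SynapseKinetics()
        inh_only = NeuronState(v=-50.0, g_gabaa=1.0, g_gabab=0.5)
        assert synaptic_current(inh_only, kin, 0.0) == synaptic_current(inh_only, kin, 1.0)
        exc_only = NeuronState(v=-50.0, g_ampa=1.0)
        assert synaptic_current(exc_only, kin, 0.5) == pytest.approx(
            0.5 * synaptic_current(exc_only, kin, 1.0)
        )


class TestConductanceKinetics:
    def test_closed_form_one_tau(self):
        kin = SynapseKinetics()
        state = NeuronState(g_ampa=1.0)
        out = decay_conductances(state, kin, kin.tau_ampa)
        assert out.g_ampa == pytest.approx(math.exp(-1.0))

    def test_superposition(self):
        kin = SynapseKinetics()
        a = decay_conductances(NeuronState(g_nmda=1.0), kin, 30.0).g_nmda
        b = decay_conductances(NeuronState(g_nmda=2.5), kin, 30.0).g_nmda
        ab = decay_conductances(NeuronState(g_nmda=3.5), kin, 30.0).g_nmda
        assert ab == pytest.approx(a + b)

    def test_increment_schedule_matches_fine_ode(self):
        # arbitrary schedule of increments vs brute-force ODE at dt/100
        kin = SynapseKinetics()
        schedule = {10: 0.3, 47: 1.1, 48: 0.2, 90: 0.7}  # step index -> increment
        dt = 1.0  # ms
        g = 0.0
        for i in range(120):
            g *= math.exp(-dt / kin.tau_gabab)
            g += schedule.get(i, 0.0)
        g_fine = 0.0
        fine = dt / 100.0
        for i in range(120 * 100):
            g_fine += -fine * g_fine / kin.tau_gabab
            if i % 100 == 0 and i // 100 in schedule:
                g_fine += schedule[i // 100]
        assert g == pytest.approx(g_fine, rel=0.01)


class TestExcitabilityFeedback:
    def test_no_spikes_keeps_e_at_steady_state(self):
        params = NeuronParams(e_ss=5.0)
        state = NeuronState(e=params.e_ss)
        for _ in range(1000):
            state = excitability_update(state, params, 1e-3, False)
        assert state.r == 0.0
        assert state.e == params.e_ss

    def test_leaky_rate_converges_to_spike_rate(self):
        # periodic spiking at f: stationary mean of the leaky estimator is f
        params = NeuronParams()
        f, dt = 8.0, 0.5e-3
        period = int(round(1.0 / f / dt))
        state = NeuronState()
        rs = []
        for i in range(int(30.0 / dt)):
            state = excitability_update(state, params, dt, i % period == 0)
            if i > int(10.0 / dt):
                rs.append(state.r)
        assert np.mean(rs) == pytest.approx(f, rel=0.02)

    def test_algebraic_feedback_arithmetic(self):
        # e_ss=10, k_e=6, stationary r=1 Hz -> e=4
        params = NeuronParams(e_ss=10.0, k_e=6.0)
        state = NeuronState(r=1.0 / math.exp(-1e-3 / params.tau_r))
        state = excitability_update(state, params, 1e-3, False)
        assert state.r == pytest.approx(1.0)
        assert state.e == pytest.approx(4.0)

    @settings(max_examples=50, deadline=None)
    @given(
        spikes=st.lists(st.booleans(), min_size=1, max_size=400),
        e_ss=st.floats(-5.0, 15.0),
    )
    def test_r_nonnegative_and_e_bounded(self, spikes, e_ss):
        params = NeuronParams(e_ss=e_ss)
        state = NeuronState(e=e_ss)
        for s in spikes:
            state = excitability_update(state, params, 1e-3, s)
            assert state.r >= 0.0
            assert state.e <= params.e_ss + 1e-12
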