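"""LIF integrator: closed-form checks, refractory law, determinism."""

import math

import numpy as np
import pytest
from scipy import sparse

import connlif as cl
from connlif import StimulusEntry, StimulusProtocol, firing_rates, \
    poisson_spike_times, simulate
from connlif.errors import ConfigurationError

from conftest import triplet_weights

P = cl.DEFAULT_PARAMS
GAP = P.v_threshold - P.v_resting  # 7 mV


def peak_factor(params=P):
    """Closed-form peak of the double-exponential PSP, per mV of weight."""
    a, b = 1.0 / params.t_mbr, 1.0 / params.tau
    tstar = math.log(b / a) / (b - a)
    return (a / (b - a)) * (math.exp(-a * tstar) - math.exp(-b * tstar))


class TestPoissonSpikeTimes:
    def test_zero_rate_empty(self):
        assert len(poisson_spike_times(0.0, 0, 1000, seed=1)) == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            poisson_spike_times(-1.0, 0, 1000, seed=1)

    def test_deterministic_given_seed(self):
        a = poisson_spike_times(80.0, 0, 1000, seed=42)
        b = poisson_spike_times(80.0, 0, 1000, seed=42)
        assert np.array_equal(a, b)

    def test_count_law(self):
        # Poisson count over many seeds: mean ~ rate*T, variance ~ mean
        counts = [len(poisson_spike_times(100.0, 0, 1000, seed=s))
                  for s in range(400)]
        assert np.mean(counts) == pytest.approx(100, abs=3 * 10 / 20)
        assert np.var(counts) == pytest.approx(100, rel=0.35)

    def test_times_within_window(self):
        t = poisson_spike_times(200.0, 100, 300, seed=7)
        assert t.min() >= 100 and t.max() < 300


class TestSingleNeuronDynamics:
    def test_isolated_neuron_stays_at_rest(self, single_neuron):
        prot = StimulusProtocol(entries=[], n_trials=1, duration_ms=100)
        rec = simulate(single_neuron, P, prot, record_v=["n0"])
        assert len(rec.trials[0]) == 0
        assert np.allclose(rec.v_traces[0]["n0"], P.v_resting)

    @pytest.mark.parametrize("g_jump", [7.5, 10.0, 14.0, 20.0])
    def test_rc_charging_first_spike_time(self, single_neuron, g_jump):
        # synaptic decay disabled: v relaxes toward V_rest + G with T_mbr
        dt = 0.1
        prot = StimulusProtocol(entries=[], n_trials=1, duration_ms=200,
                                injections=(("n0", 0.0, g_jump),))
        rec = simulate(single_neuron, P.replace(tau=math.inf), prot, dt=dt)
        predicted = -P.t_mbr * math.log(1 - GAP / g_jump)
        assert rec.trials[0]["n0"][0] == pytest.approx(predicted, abs=2 * dt)

    def test_subthreshold_jump_never_fires(self, single_neuron):
        prot = StimulusProtocol(entries=[], n_trials=1, duration_ms=300,
                                injections=(("n0", 0.0, GAP - 0.1),))
        rec = simulate(single_neuron, P.replace(tau=math.inf), prot)
        assert len(rec.trials[0]) == 0

    def test_single_psp_peak_matches_double_exponential(self, single_neuron):
        w = P.w_syn
        prot = StimulusProtocol(entries=[], n_trials=1, duration_ms=60,
                                injections=(("n0", 0.0, w),))
        rec = simulate(single_neuron, P, prot, dt=0.01, record_v=["n0"])
        peak = rec.v_traces[0]["n0"].max() - P.v_resting
        assert peak == pytest.approx(w * peak_factor(), rel=1e-4)
        assert peak < GAP  # one synapse is far subthreshold

    def test_minimum_simultaneous_synapses_to_fire(self, single_neuron):
        n_star = math.ceil(GAP / (peak_factor() * P.w_syn))

        def fires(n, dt):
            prot = StimulusProtocol(entries=[], n_trials=1, duration_ms=60,
                                    injections=(("n0", 0.0, n * P.w_syn),))
            return len(simulate(single_neuron, P, prot, dt=dt).trials[0]) > 0

        assert fires(n_star, 0.1) and not fires(n_star - 1, 0.1)
        # fine-dt oracle confirms the closed-form count
        assert fires(n_star, 0.005) and not fires(n_star - 1, 0.005)


class TestRefractoryAndRates:
    def test_forced_rate_follows_dead_time_law(self, single_neuron):
        rate = 100.0
        prot = StimulusProtocol(
            entries=[StimulusEntry(("n0",), rate)], n_trials=30,
            duration_ms=1000.0, seed=9)
        rt = firing_rates(simulate(single_neuron, P, prot))
        dead = P.t_refractory / 1000.0
        predicted = rate / (1 + rate * dead)
        mu = 1 / rate + dead          # renewal ISI mean (s)
        sd_rate = math.sqrt((1 / rate ** 2) / (mu ** 3 * 30.0))
        assert abs(rt.loc["n0", "rate_hz"] - predicted) <= 3 * sd_rate

    def test_no_isi_below_refractory_period(self, chain_weights):
        sensory = [i for i in chain_weights.neuron_ids if i.startswith("l0")]
        prot = StimulusProtocol(entries=[StimulusEntry(tuple(sensory), 150.0)],
                                n_trials=5, duration_ms=500.0, seed=2)
        rec = simulate(chain_weights, P, prot, dt=0.1)
        for trial in rec.trials:
            for times in trial.values():
                if len(times) > 1:
                    assert np.diff(times).min() >= P.t_refractory - 0.1

    def test_firing_rate_arithmetic(self, single_neuron):
        rec = cl.SpikeRecord(
            trials=[{"n0": np.arange(10.0)}, {"n0": np.arange(20.0)}],
            neuron_ids=("n0",), duration_ms=1000.0, dt=0.1, seed=0)
        rt = firing_rates(rec)
        assert rt.loc["n0", "rate_hz"] == pytest.approx(15.0)

    def test_silent_neurons_reported_at_zero(self, chain_weights):
        prot = StimulusProtocol(entries=[], n_trials=2, duration_ms=100.0)
        rt = firing_rates(simulate(chain_weights, P, prot))
        assert (rt["rate_hz"] == 0).all()

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValueError):
            firing_rates([])


class TestNetworkSemantics:
    def test_determinism(self, chain_weights):
        prot = StimulusProtocol(
            entries=[StimulusEntry(("l0n0", "l0n1"), 120.0)], n_trials=3,
            duration_ms=300.0, seed=4)
        r1 = simulate(chain_weights, P, prot)
        r2 = simulate(chain_weights, P, prot)
        for a, b in zip(r1.trials, r2.trials):
            assert set(a) == set(b)
            for nid in a:
                assert np.array_equal(a[nid], b[nid])

    def test_undriven_inhibitory_neuron_changes_nothing(self, params):
        # the zero-basal-rate consequence: inhibition onto a silent network
        # is inert, bit-exactly
        base = [("s0", "m0", 6.0), ("s1", "m0", 6.0), ("s0", "s1", 3.0)]
        w0 = triplet_weights(base)
        w1 = triplet_weights(base + [("inh0", "m0", -50.0),
                                     ("inh0", "s1", -50.0)])
        prot = StimulusProtocol(entries=[StimulusEntry(("s0",), 120.0)],
                                n_trials=4, duration_ms=400.0, seed=8)
        r0 = simulate(w0, params, prot)
        r1 = simulate(w1, params, prot)
        for a, b in zip(r0.trials, r1.trials):
            assert set(a) == set(b)
            for nid in a:
                assert np.array_equal(a[nid], b[nid])

    def test_transmission_delay_respected(self, params):
        w = triplet_weights([("pre", "post", 50.0)])
        prot = StimulusProtocol(entries=[], n_trials=1, duration_ms=50.0,
                                forced_spikes={"pre": [10.0]})
        rec = simulate(w, params, prot, dt=0.1)
        t_post = rec.trials[0]["post"][0]
        assert t_post >= 10.0 + params.t_dly

    def test_dt_exceeding_delay_is_config_error(self, single_neuron):
        prot = StimulusProtocol(entries=[], n_trials=1, duration_ms=10.0)
        with pytest.raises(ConfigurationError):
            simulate(single_neuron, P, prot, dt=2.0)

    def test_synapse_stim_mode_also_drives_firing(self, single_neuron):
        prot = StimulusProtocol(entries=[StimulusEntry(("n0",), 100.0)],
                                n_trials=2, duration_ms=500.0, seed=3)
        rec = simulate(single_neuron, P, prot, stim_mode="synapse")
        rt = firing_rates(rec)
        assert rt.loc["n0", "rate_hz"] > 0

    def test_threshold_shift_invariance(self, params):
        # shifting all potentials by a constant leaves spike trains intact
        w = triplet_weights([("s", "m", 8.0)])
        prot = StimulusProtocol(entries=[StimulusEntry(("s",), 150.0)],
                                n_trials=2, duration_ms=300.0, seed=5)
        shifted = params.replace(v_resting=params.v_resting + 10,
                                 v_reset=params.v_reset + 10,
                                 v_threshold=params.v_threshold + 10)
        r0 = simulate(w, params, prot)
        r1 = simulate(w, shifted, prot)
        for a, b in zip(r0.trials, r1.trials):
            assert set(a) == set(b)
            for nid in a:
                assert np.array_equal(a[nid], b[nid])
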