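"""Cross-checks of the jitted network engine against the scalar references.

The engine must agree with (i) the scalar membrane integrator on
deterministic coupled dynamics, (ii) direct kernel summation for the
synaptic drive, and (iii) the event-driven trace implementation of the
plasticity rule -- these three references are independent of the engine's
exponential-accumulator/ring-buffer machinery.
"""

import numpy as np
import pytest

from tacsim._engine import run_network
from tacsim.core_dynamics import (
    NeuronParams,
    NeuronState,
    NoiseSpec,
    SpikeRecord,
    StimulusSpec,
    membrane_step,
)
from tacsim.network_builders import (
    LayerConfig,
    NeuronArray,
    NetworkSpec,
    build_cortical_layer,
    build_pair_motif,
)
from tacsim.plasticity import OnlineSTDP, STDPParams
from tacsim.synapses import SynapseTable, total_synaptic_drive
from tests.test_synapses import single_synapse_table


def small_random_net(n=10, seed=0, conductance=False):
    """Dense-ish random current-mode network with dt-aligned delays."""
    rng = np.random.default_rng(seed)
    pre, post = [], []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < 0.4:
                pre.append(i)
                post.append(j)
    m = len(pre)
    tab = SynapseTable(
        pre=np.array(pre),
        post=np.array(post),
        weight=np.full(m, 0.1),
        delay=rng.choice([0.5, 0.7, 1.0], m),
        receptor=np.zeros(m, np.int64),
        plastic=np.ones(m, bool),
        g0=np.full(m, 0.1),
        cell_type_pre=np.zeros(m, np.int64),
        cell_type_post=np.zeros(m, np.int64),
        conductance_mode=conductance,
    )
    neurons = NeuronArray(
        tau_m=rng.uniform(6.0, 14.0, n),
        v_rest=np.full(n, -60.0),
        cell_type=np.zeros(n, np.int64),
        layer=np.full(n, -1, np.int64),
        rheobase_offset=np.zeros(n),
    )
    return NetworkSpec(neurons=neurons, synapses=tab, metadata={})


class TestEngineVsScalarIntegrator:
    def test_deterministic_pair_matches_scalar_reference(self):
        """sigma = 0 suprathreshold pair: engine spike trains equal a step-by-
        step scalar simulation using membrane_step + direct drive summation."""
        net = build_pair_motif(10.0, 14.0)
        noise = NoiseSpec(mu=7.0, sigma=0.0)
        stim = StimulusSpec.sham()
        dt, t_end = 0.1, 1000.0

        res = run_network(build_pair_motif(10.0, 14.0), stim, noise, t_end / 1000.0,
                          seed=0, dt=dt, stdp=None)

        params = [NeuronParams(tau_m=10.0), NeuronParams(tau_m=14.0)]
        states = [NeuronState(v=-60.0), NeuronState(v=-60.0)]
        ids, times = [], []
        n_steps = int(round(t_end / dt))
        hist = SpikeRecord(np.zeros(0, int), np.zeros(0), t_end, 2)
        for k in range(n_steps):
            t = k * dt
            drives = [
                total_synaptic_drive(i, t, hist, net.synapses, states[i].v,
                                     cutoff_factor=1e9)
                for i in range(2)
            ]
            for i in range(2):
                states[i], spiked = membrane_step(
                    states[i], drives[i], params[i], noise, stim, t, dt
                )
                if spiked:
                    ids.append(i)
                    times.append(t + dt)
                    hist = SpikeRecord(np.array(ids), np.array(times), t_end, 2)
        ref = SpikeRecord(np.array(ids), np.array(times), t_end, 2)
        got = SpikeRecord(res.spike_ids, res.spike_times, t_end, 2)
        assert len(got) == len(ref) > 10
        assert np.array_equal(got.ids, ref.ids)
        np.testing.assert_allclose(got.times, ref.times, atol=1e-9)


class TestDriveAccumulators:
    def test_accumulators_match_direct_summation(self):
        """Per-neuron drive from the exponential accumulators equals direct
        double-exponential summation over the spike history (1e-9 relative)."""
        net = small_random_net(n=10, seed=1)
        noise = NoiseSpec(mu=5.5, sigma=1.0)
        dur = 0.5
        res = run_network(
            net,
            StimulusSpec.sham(),
            noise,
            dur,
            seed=2,
            dt=0.1,
            stdp=None,
            group_id=np.arange(10),
            n_groups=10,
        )
        spikes = SpikeRecord(res.spike_ids, res.spike_times, dur * 1000, 10)
        assert len(spikes) > 20
        peak = np.abs(res.drive_traces).max()
        for k in (1000, 2500, 4999):
            t = k * 0.1
            for i in range(10):
                direct = total_synaptic_drive(i, t, spikes, net.synapses, 0.0,
                                              cutoff_factor=1e9)
                assert res.drive_traces[k, i] == pytest.approx(
                    direct, abs=1e-9 * max(peak, 1.0)
                )


class TestEngineStdp:
    def test_engine_weights_match_trace_reference(self):
        """Engine in-loop plasticity equals the event-driven OnlineSTDP replay
        of the same spike train (clipping included)."""
        net = small_random_net(n=10, seed=3)
        w0 = net.synapses.weight.copy()
        p = STDPParams(g_0=0.1)
        res = run_network(
            net, StimulusSpec.sham(), NoiseSpec(mu=5.5, sigma=1.0), 1.0,
            seed=4, dt=0.1, stdp=p,
        )
        spikes = SpikeRecord(res.spike_ids, res.spike_times, 1000.0, 10)
        assert len(spikes) > 30

        ref = small_random_net(n=10, seed=3)  # identical wiring, fresh weights
        assert np.array_equal(ref.synapses.weight, w0)
        online = OnlineSTDP(ref.synapses, p, n_neurons=10)
        for t in np.unique(spikes.times):
            online.process(spikes.ids[spikes.times == t], t)
        np.testing.assert_allclose(net.synapses.weight, ref.synapses.weight,
                                   rtol=1e-9, atol=1e-12)

    def test_weights_never_leave_bounds(self):
        net = small_random_net(n=10, seed=5)
        res = run_network(
            net, StimulusSpec(amplitude=1.0, frequency=25.0, t_on=0.0, t_off=2.0),
            NoiseSpec(mu=5.5, sigma=1.0), 2.0, seed=6, dt=0.1,
            stdp=STDPParams(g_0=0.1),
            snapshot_times_s=np.arange(0.2, 2.01, 0.2),
        )
        assert res.weight_snaps.min() >= 0.001 - 1e-12
        assert res.weight_snaps.max() <= 0.2 + 1e-12

    def test_refractory_enforced_in_spike_trains(self):
        net = small_random_net(n=10, seed=7)
        res = run_network(net, StimulusSpec.sham(), NoiseSpec(mu=6.5, sigma=1.0),
                          1.0, seed=8, dt=0.1, stdp=None)
        spikes = SpikeRecord(res.spike_ids, res.spike_times, 1000.0, 10)
        for i in range(10):
            isis = np.diff(spikes.train(i))
            if isis.size:
                assert isis.min() >= net.neurons.tau_ref


class TestEntrainmentBandwidth:
    def test_fast_membrane_locks_at_higher_frequencies(self):
        """Deterministic subthreshold neuron (mu = 5.9 mV, sigma = 0,
        A_s = 0.5 mV, no refractory period): the 6 ms membrane stays 1:1
        phase-locked at 25 and 35 Hz while the 14 ms membrane skips cycles."""
        from tacsim._engine import simulate_unconnected

        def spikes_per_cycle(tau, omega):
            res = simulate_unconnected(
                np.array([tau]), np.zeros(1), np.array([-60.0]),
                v_thr=-54.0, tau_ref=0.0, mu=5.9, sigma=0.0,
                stim=StimulusSpec(amplitude=0.5, frequency=omega,
                                  t_on=0.0, t_off=10.0),
                duration_s=10.0, dt=0.1, seed=1, record_spikes=True,
            )
            ph = (2 * np.pi * omega * res.spike_times / 1000.0) % (2 * np.pi)
            vs = abs(np.exp(1j * ph).mean()) if res.counts[0] else 0.0
            return res.counts[0] / (10.0 * omega), vs

        for omega in (25.0, 35.0):
            fast_spc, fast_vs = spikes_per_cycle(6.0, omega)
            slow_spc, _ = spikes_per_cycle(14.0, omega)
            assert abs(fast_spc - 1.0) < 0.05 and fast_vs > 0.99
            assert slow_spc < 0.7


class TestDeterminism:
    def test_identical_seeds_bit_identical_records(self):
        cfg = LayerConfig(n_total=250)
        a = build_cortical_layer(cfg, seed=9)
        b = build_cortical_layer(cfg, seed=9)
        ra = run_network(a, StimulusSpec.sham(), NoiseSpec(), 1.0, seed=10, dt=0.1,
                         stdp=STDPParams())
        rb = run_network(b, StimulusSpec.sham(), NoiseSpec(), 1.0, seed=10, dt=0.1,
                         stdp=STDPParams())
        assert np.array_equal(ra.spike_ids, rb.spike_ids)
        assert np.array_equal(ra.spike_times, rb.spike_times)
        assert np.array_equal(a.synapses.weight, b.synapses.weight)
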