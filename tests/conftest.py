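"""Shared fixtures.

The heavyweight network protocol runs are session-scoped so that several
tests (rates, entrainment, weight dynamics, amplitude contrasts) can reuse a
single simulation.  Problem sizes follow the desk-scale defaults: a
2000-neuron balanced layer and a 4 x 600 laminar network, with shortened
epoch schedules relative to the full-length 4/40/60 s protocol.
"""

from __future__ import annotations

import numpy as np
import pytest

from tacsim.core_dynamics import NoiseSpec, StimulusSpec
from tacsim.network_builders import LayerConfig, build_cortical_layer, build_multilayer
from tacsim.protocols import EpochSchedule, run_protocol
from tacsim.synthetic_inputs import MTCDistributionSpec, calibrated_layer_profiles

#: schedule used by the layer-scale fixtures: 2 s pre, 15 s stim, 8 s post
LAYER_SCHEDULE = EpochSchedule(2.0, 17.0, 25.0)
STIM_25 = StimulusSpec(amplitude=1.0, frequency=25.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sham_layer_run():
    """10 s sham (amplitude 0) run of the desk-scale heterogeneous layer."""
    net = build_cortical_layer(seed=101)
    rec = run_protocol(
        net,
        EpochSchedule(5.0, 5.0, 10.0),
        StimulusSpec.sham(),
        seed=101,
        snapshot_every_s=1.0,
    )
    return net, rec


@pytest.fixture(scope="session")
def stim_layer_run():
    """Heterogeneous layer entrained at 25 Hz, amplitude 1 mV."""
    net = build_cortical_layer(seed=102)
    rec = run_protocol(net, LAYER_SCHEDULE, STIM_25, seed=102, record_groups=True)
    return net, rec


@pytest.fixture(scope="session")
def homogeneous_layer_run():
    """Timescale-homogeneous control (sigma_tau = 0) entrained at 25 Hz."""
    cfg = LayerConfig(mtc=MTCDistributionSpec(mean=10.0, sd=0.0))
    net = build_cortical_layer(cfg, seed=103)
    rec = run_protocol(net, EpochSchedule(2.0, 17.0, 20.0), STIM_25, seed=103)
    return net, rec


@pytest.fixture(scope="session")
def lowamp_layer_run():
    """Low-amplitude regime: 0.2 mV at 25 Hz on the heterogeneous layer."""
    net = build_cortical_layer(seed=102)
    rec = run_protocol(
        net,
        LAYER_SCHEDULE,
        StimulusSpec(amplitude=0.2, frequency=25.0),
        seed=102,
    )
    return net, rec


@pytest.fixture(scope="session")
def pair_grid():
    """Two-neuron motif runs over the reduced (tau_post x omega) grid.

    For every cell: per-trial forward-weight change (stim-end average minus
    initial) and the spike-timing-difference histogram measured during the
    stimulation epoch.  Five trials per cell with seeds derived from one
    master seed.
    """
    from tacsim import analysis_metrics as am
    from tacsim.network_builders import build_pair_motif
    from tacsim.protocols import child_seeds

    sched = EpochSchedule(1.0, 11.0, 12.0)
    seeds = child_seeds(7, 5)
    out = {}
    for tau_post in (6.0, 10.0, 14.0):
        for omega in (5.0, 15.0, 25.0, 35.0):
            dgs, hists = [], []
            for s in seeds:
                net = build_pair_motif(10.0, tau_post)
                rec = run_protocol(
                    net,
                    sched,
                    StimulusSpec(amplitude=1.0, frequency=omega),
                    seed=int(s),
                )
                w_end = rec.snaps_between(6.0, 11.0).mean(axis=0)
                dgs.append(w_end[0] - rec.initial_weights[0])
                stim_spikes = rec.spikes.window(1000.0, 11000.0)
                hists.append(
                    am.delta_t_histogram(stim_spikes.train(0), stim_spikes.train(1))
                )
            out[(tau_post, omega)] = (np.array(dgs), hists)
    # sham runs for the no-stimulation control
    for tau_post in (6.0, 14.0):
        dgs = []
        for s in seeds:
            net = build_pair_motif(10.0, tau_post)
            rec = run_protocol(net, sched, StimulusSpec.sham(), seed=int(s))
            w_end = rec.snaps_between(6.0, 11.0).mean(axis=0)
            dgs.append(w_end[0] - rec.initial_weights[0])
        out[(tau_post, "sham")] = (np.array(dgs), None)
    return out


@pytest.fixture(scope="session")
def laminar_profiles():
    return calibrated_layer_profiles(seed=104)


@pytest.fixture(scope="session")
def laminar_runs(laminar_profiles):
    """Four-layer laminar network: sham and 10 Hz stimulated runs."""
    sched = EpochSchedule(2.0, 17.0, 20.0)
    out = {}
    for name, amp in (("sham", 0.0), ("stim", 1.0)):
        net = build_multilayer(profiles=laminar_profiles, seed=105)
        rec = run_protocol(
            net,
            sched,
            StimulusSpec(amplitude=amp, frequency=10.0),
            seed=105,
        )
        out[name] = (net, rec)
    return out
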