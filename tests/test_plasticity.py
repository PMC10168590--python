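"""STDP rule: pointwise values, soft bounds, online traces vs all-pairs oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tacsim.plasticity import (
    DeltaTHistogram,
    OnlineSTDP,
    STDPParams,
    clip_weight,
    predicted_mean_change,
    stdp_delta,
    stdp_fixed_point,
)
from tests.test_synapses import single_synapse_table


def brute_force_stdp(pre_times, post_times, g0, params, table_g0=None):
    """Sequential all-pairs oracle: replay spike events in time order and, at
    each event, sum the exponential pairwise terms of the learning rule over
    all earlier partner spikes, updating the weight sequentially without
    clipping.  Coincident pre/post spikes pair with dT = 0 and contribute
    nothing; within one timestamp potentiation applies before depression,
    matching the online trace implementation.
    """
    gref = g0 if table_g0 is None else table_g0
    g = g0
    events = sorted(set(list(pre_times) + list(post_times)))
    for t in events:
        if t in post_times:  # potentiation from all earlier pre spikes
            s = sum(math.exp(-(t - tp) / params.gamma_plus) for tp in pre_times if tp < t)
            g = g + params.a_plus * gref * (1.0 - g / (params.g_max_factor * gref)) * s
        if t in pre_times:  # depression from all earlier post spikes
            s = sum(math.exp(-(t - tq) / params.gamma_minus) for tq in post_times if tq < t)
            g = g - params.a_minus * g * s
    return g


class TestStdpDelta:
    def test_decays_to_zero_at_large_lag(self):
        p = STDPParams()
        assert stdp_delta(0.5, 1e4, p) == pytest.approx(0.0, abs=1e-12)
        assert stdp_delta(0.5, -1e4, p) == pytest.approx(0.0, abs=1e-12)

    def test_potentiation_vanishes_at_gmax(self):
        p = STDPParams()
        assert stdp_delta(p.g_max, 5.0, p) == 0.0

    def test_reference_value_at_plus_ten_ms(self):
        # g -> 0 limit, dT = +10 ms, A_+ = 0.02, gamma_+ = 10 ms
        p = STDPParams()
        assert stdp_delta(0.0, 10.0, p) == pytest.approx(0.02 * math.exp(-1.0), rel=1e-12)

    def test_coincident_pair_contributes_nothing(self):
        assert stdp_delta(0.5, 0.0, STDPParams()) == 0.0

    def test_scales_with_baseline_weight(self):
        # fractional rates: the same dT moves a motif weight (g_0 = 0.1) by
        # 1000x less than a unit-baseline weight
        big = stdp_delta(0.0, 10.0, STDPParams(g_0=1.0))
        small = stdp_delta(0.0, 10.0, STDPParams(g_0=1e-3))
        assert small == pytest.approx(big * 1e-3, rel=1e-12)

    @given(st.floats(-80, 80), st.floats(0.01, 1.99))
    @settings(max_examples=100, deadline=None)
    def test_sign_follows_timing(self, dt, g_rel):
        p = STDPParams()
        dg = stdp_delta(g_rel * p.g_0, dt, p)
        if dt > 0:
            assert dg >= 0
        elif dt < 0:
            assert dg <= 0


class TestClipWeight:
    def test_clips_above(self):
        p = STDPParams(g_0=0.1)
        assert clip_weight(0.3, p) == pytest.approx(0.2)  # 2 g_0

    def test_clips_below(self):
        p = STDPParams(g_0=0.1)
        assert clip_weight(0.0, p) == pytest.approx(0.001)  # 0.01 g_0

    def test_interior_untouched(self):
        p = STDPParams(g_0=0.1)
        assert clip_weight(0.1, p) == 0.1


class TestOnlineSTDP:
    def test_lone_pre_spike_changes_nothing(self):
        tab = single_synapse_table(g=0.1)
        online = OnlineSTDP(tab, STDPParams(g_0=0.1), n_neurons=2)
        online.process([0], 1.0)
        assert tab.weight[0] == 0.1

    def test_single_pair_equals_pointwise_rule(self):
        tab = single_synapse_table(g=0.1)
        p = STDPParams(g_0=0.1)
        online = OnlineSTDP(tab, p, n_neurons=2)
        online.process([0], 0.0)  # pre
        online.process([1], 10.0)  # post, dT = +10
        assert tab.weight[0] == pytest.approx(0.1 + stdp_delta(0.1, 10.0, p), rel=1e-12)

    def test_matches_brute_force_all_pairs(self):
        """Cumulative online trace updates equal the sequential all-pairs sum
        on Poisson spike trains, with clipping disabled, to 1e-9."""
        rng = np.random.default_rng(7)
        pre = np.unique(np.round(np.cumsum(rng.exponential(30.0, 60)), 1))
        post = np.unique(np.round(np.cumsum(rng.exponential(25.0, 60)), 1))
        tab = single_synapse_table(g=0.1)
        p = STDPParams(g_0=0.1)
        online = OnlineSTDP(tab, p, n_neurons=2, clip=False)
        events = sorted(set(pre) | set(post))
        for t in events:
            who = []
            if t in pre:
                who.append(0)
            if t in post:
                who.append(1)
            online.process(who, t)
        expected = brute_force_stdp(set(pre), set(post), 0.1, p)
        assert tab.weight[0] == pytest.approx(expected, abs=1e-9 * 0.1)


class TestPredictor:
    def flat_hist(self, window=100.0, nbins=200):
        edges = np.linspace(-window, window, nbins + 1)
        dens = np.full(nbins, 1.0 / (2 * window))
        return DeltaTHistogram(edges=edges, density=dens, window=window)

    def test_symmetric_f_equal_rates_is_zero(self):
        p = STDPParams(a_plus=0.01, a_minus=0.01)
        assert predicted_mean_change(self.flat_hist(), p) == pytest.approx(0.0, abs=1e-15)

    def test_point_mass_value(self):
        p = STDPParams()
        edges = np.array([4.5, 5.5])
        hist = DeltaTHistogram(edges=edges, density=np.array([1.0]), window=100.0)
        assert predicted_mean_change(hist, p) == pytest.approx(
            0.02 * math.exp(-0.5), rel=1e-12
        )

    def test_operating_point_removes_flat_bias(self):
        p = STDPParams()  # A_+ = 2 A_-: bare form is biased on a flat f
        assert predicted_mean_change(self.flat_hist(), p) > 0
        balanced = predicted_mean_change(self.flat_hist(), p, g=p.g_0)
        assert balanced == pytest.approx(0.0, abs=1e-12)

    def test_left_shifted_distribution_predicts_depression(self):
        edges = np.array([-10.5, -9.5])
        hist = DeltaTHistogram(edges=edges, density=np.array([1.0]), window=100.0)
        assert predicted_mean_change(hist, STDPParams()) < 0

    def test_unnormalised_histogram_rejected(self):
        edges = np.array([-1.0, 0.0, 1.0])
        hist = DeltaTHistogram(edges=edges, density=np.array([1.0, 2.0]), window=1.0)
        with pytest.raises(ValueError):
            predicted_mean_change(hist, STDPParams())


class TestFixedPoint:
    def test_default_fixed_point_is_baseline(self):
        p = STDPParams()
        assert stdp_fixed_point(p) == pytest.approx(p.g_0, rel=1e-12)

    def test_fixed_point_balances_rates(self):
        p = STDPParams(a_plus=0.03, a_minus=0.007, gamma_plus=8.0, gamma_minus=14.0)
        g = stdp_fixed_point(p)
        lhs = p.a_plus * (1 - g / p.g_max) * p.gamma_plus
        rhs = p.a_minus * (g / p.g_0) * p.gamma_minus
        assert lhs == pytest.approx(rhs, rel=1e-12)
        assert p.g_min < g < p.g_max
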