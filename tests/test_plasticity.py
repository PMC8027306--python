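"""Plasticity rules: traces, regime limits, PSTH kernel fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tempocode.network import SpikeRecord
from tempocode.plasticity import (CalibrationError, PsthCurve, TraceParams,
                                  compute_mean_postspike_time, compute_psth,
                                  fit_scale_bias, fixed_time_update,
                                  psth_trace, psth_trace_per_pixel,
                                  psth_update, stdp_update, trace_at,
                                  update_trace)
from tempocode.events import EventStream, LabeledDataset


def brute_force_trace(spike_times, t_eval, p: TraceParams, h=0.01):
    """Per-0.01 ms integration of the trace ODE — the independent oracle."""
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    decay = 1.0 if math.isinf(p.tau_xpre) else math.exp(-h / p.tau_xpre)
    x = 0.0
    i = 0
    n = round(t_eval / h)
    for step in range(n):
        t = step * h
        while i < len(spike_times) and spike_times[i] <= t + 1e-9:
            x += p.dx_pre
            i += 1
        x *= decay
    while i < len(spike_times) and spike_times[i] <= t_eval + 1e-9:
        x += p.dx_pre
        i += 1
    return x


class TestTrace:
    def test_closed_form_decay(self):
        p = TraceParams(tau_xpre=50.0)
        assert update_trace(1.0, 50.0, 0, p) == pytest.approx(math.exp(-1))

    def test_fresh_spikes_add_increments(self):
        p = TraceParams(dx_pre=0.4)
        assert update_trace(0.0, 10.0, 3, p) == pytest.approx(1.2)

    def test_negative_elapsed_rejected(self):
        with pytest.raises(ValueError):
            update_trace(1.0, -1.0, 0, TraceParams())

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10_000))
    def test_event_driven_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = TraceParams(tau_xpre=float(rng.uniform(5, 300)),
                        dx_pre=float(rng.uniform(0.1, 2.0)))
        n = int(rng.integers(1, 25))
        # spikes on the 0.01 ms grid so both integrators see the same input
        times = np.sort(rng.integers(0, 10_000, size=n)) * 0.01
        t_eval = 105.0
        fast = trace_at(times, t_eval, p)
        slow = brute_force_trace(times, t_eval, p)
        assert fast == pytest.approx(slow, rel=1e-9)


class TestStdpUpdate:
    def test_zero_at_target_trace(self):
        p = TraceParams(x_tar=3.0)
        assert stdp_update(0.4, 3.0, p) == 0.0

    def test_zero_at_weight_ceiling(self):
        p = TraceParams(mu=0.9)
        assert stdp_update(p.w_max, 10.0, p) == 0.0

    def test_mu_zero_weight_independent(self):
        p = TraceParams(mu=0.0, eta=0.1, x_tar=1.0)
        assert stdp_update(0.2, 4.0, p) == stdp_update(0.9, 4.0, p) \
            == pytest.approx(0.3)


class TestRegimeLimits:
    def test_rate_limit_permutation_invariant_bitwise(self):
        # decay disabled: the trace is dx_pre * count, independent of order
        p = TraceParams(tau_xpre=math.inf, dx_pre=1.0)
        rng = np.random.default_rng(0)
        times = rng.uniform(0, 100, size=40)
        w = 0.37
        base = stdp_update(w, trace_at(times, 100.0, p), p)
        for _ in range(5):
            rng.shuffle(times)
            assert stdp_update(w, trace_at(times, 100.0, p), p) == base

    def test_timing_limit_shift_by_two_tau_scales_e2(self):
        T = 105.0
        p = TraceParams(tau_xpre=T / 10.0)
        post = 80.0
        near = trace_at(np.array([post - p.tau_xpre]), post, p)
        far = trace_at(np.array([post - 3 * p.tau_xpre]), post, p)
        assert far / near == pytest.approx(math.exp(-2), abs=1e-6)


class TestFixedTime:
    def test_mean_postspike_time(self):
        recs = [SpikeRecord(np.array([0]), np.array([100.0]), 105.0),
                SpikeRecord(np.array([1]), np.array([104.0]), 105.0)]
        assert compute_mean_postspike_time(recs) == 102.0
        assert compute_mean_postspike_time(recs[::-1]) == 102.0

    def test_single_record(self):
        rec = SpikeRecord(np.array([2]), np.array([88.0]), 105.0)
        assert compute_mean_postspike_time([rec]) == 88.0

    def test_empty_record_rejected(self):
        empty = SpikeRecord(np.array([], dtype=int), np.array([]), 105.0)
        with pytest.raises(ValueError):
            compute_mean_postspike_time([empty])

    def test_matches_stdp_update_at_actual_spike_time(self):
        p = TraceParams(tau_xpre=50.0)
        times = np.array([10.0, 30.0, 55.0])
        t_post = 60.0
        x = trace_at(times, t_post, p)
        assert fixed_time_update(0.5, x, p) == stdp_update(0.5, x, p)

    def test_no_presyn_spikes_gives_depression(self):
        p = TraceParams(x_tar=2.0)
        x = trace_at(np.array([]), 50.0, p)
        assert x == 0.0
        assert fixed_time_update(0.5, x, p) < 0


def _one_event_dataset():
    streams = []
    for _ in range(2):
        streams.append(EventStream.from_arrays([50], [0], [0], [1], 4, 4,
                                               duration=105, label=0))
    return LabeledDataset(streams, np.zeros(2, dtype=np.int64))


class TestPsth:
    def test_hand_computed_histogram(self):
        H_prime, H = compute_psth(_one_event_dataset(), dt_bin=1.0, T_ms=105)
        assert H_prime[50] == 2.0
        assert H[50] == 1.0
        assert H_prime.sum() == 2.0

    def test_no_events_gives_zero_histogram(self):
        ds = LabeledDataset([EventStream.empty(4, 4, duration=105, label=0)],
                            np.zeros(1, dtype=np.int64))
        H_prime, H = compute_psth(ds, T_ms=105)
        assert np.all(H == 0.0)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            compute_psth(LabeledDataset([], np.array([], dtype=np.int64)))

    def test_total_count_conserved(self, rate_dataset_small):
        from tempocode.pipelines import prepare_dataset
        train, _ = rate_dataset_small
        ms = prepare_dataset(train)
        H_prime, _ = compute_psth(ms, T_ms=105)
        assert H_prime.sum() == sum(len(s) for s in ms.streams)


class TestFitScaleBias:
    def test_unimodal_histogram_gives_depressing_tails(self):
        t = np.arange(105) + 0.5
        H = 20 * 0.5 * (1 - np.cos(2 * np.pi * t / 105))
        curve = fit_scale_bias(H, reference_magnitude=0.05)
        assert curve.h[0] < 0 and curve.h[-1] < 0
        assert curve.h[52] > 0
        assert curve.ltd_area() > curve.ltp_area()
        assert curve.ltd_area() == pytest.approx(1.1 * curve.ltp_area(),
                                                 rel=1e-6)

    def test_constant_histogram_warns_of_no_potentiation(self):
        # a flat histogram admits only a flat (purely depressing) kernel
        H = np.full(50, 3.0)
        with pytest.warns(RuntimeWarning, match="no potentiating"):
            curve = fit_scale_bias(H, reference_magnitude=0.05)
        assert curve.ltp_area() == 0.0
        assert curve.ltd_area() > 0.0

    def test_degenerate_histogram_rejected(self):
        with pytest.raises(CalibrationError):
            fit_scale_bias(np.zeros(10), reference_magnitude=0.05)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(CalibrationError):
            fit_scale_bias(np.ones(10) + np.arange(10), 0.0)

    def test_curve_invariant_enforced_by_type(self):
        with pytest.raises(ValueError, match="LTD"):
            PsthCurve(dt_bin=1.0, H=np.ones(4), a=1.0, b=1.0, N_patterns=1)


class TestPsthTrace:
    def _curve(self):
        H = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        return PsthCurve(dt_bin=1.0, H=H, a=1.0, b=-2.5, N_patterns=1)

    def test_silent_neuron_depressed_by_x_tar(self):
        assert psth_trace(np.array([]), self._curve(), x_tar=2.0) == -2.0

    def test_sum_of_h_at_spike_bins(self):
        curve = self._curve()
        # spikes in bins 1 and 2: h = -0.5 and 0.5 -> sum 0
        assert psth_trace(np.array([1.2, 2.8]), curve, 2.0) == \
            pytest.approx(curve.h[1] + curve.h[2])

    def test_spike_in_depressing_bin_negative(self):
        assert psth_trace(np.array([0.5]), self._curve(), 2.0) < 0

    def test_vectorised_form_matches_scalar(self):
        curve = self._curve()
        s = EventStream.from_arrays([0, 2, 2], [0, 0, 1], [0, 0, 0],
                                    [1, 1, 1], 2, 2, duration=5)
        x = psth_trace_per_pixel(s, curve, x_tar=2.0, n_inputs=4)
        assert x[0] == pytest.approx(curve.h[0] + curve.h[2])
        assert x[1] == pytest.approx(curve.h[2])
        assert x[2] == -2.0 and x[3] == -2.0


class TestPsthUpdate:
    def test_zero_trace_zero_update(self):
        assert psth_update(0.3, 0.0, TraceParams()) == 0.0

    def test_saturated_weight_zero_update(self):
        p = TraceParams(mu=0.9)
        assert psth_update(p.w_max, 5.0, p) == 0.0

    def test_sign_follows_trace(self):
        p = TraceParams()
        assert psth_update(0.3, 2.0, p) > 0 > psth_update(0.3, -2.0, p)
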