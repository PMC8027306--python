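"""LIF/WTA simulation: dynamics, escalation, resets, SOM neighbourhood."""

import math

import numpy as np
import pytest

from tempocode.events import EventStream
from tempocode.network import (EscalationError, NetworkConfig, NeuronParams,
                               SomConfig, SynapseKernels, init_state,
                               periodic_reset_schedule, present_with_escalation,
                               rate_mode_config, reset_between_patterns,
                               simulate_pattern, som_scale,
                               temporal_mode_config)
from tempocode.plasticity import TraceParams


def lif_isi_closed_form(p: NeuronParams, I: float) -> float:
    """Independent oracle: inter-spike interval of a LIF under constant drive."""
    v_inf = p.V_rest + I * p.tau_M
    assert v_inf > p.v_thresh, "drive must be suprathreshold"
    return p.t_refrac + p.tau_M * math.log(
        (v_inf - p.V_reset) / (v_inf - p.v_thresh))


def _single_neuron_config(I, dt=0.5, T=500.0, t_refrac=5.0):
    return NetworkConfig(
        mode="rate", N_e=1, A_xe=0.0, dA_xe=0.0, bias_current=I,
        presentation_T=T, dt=dt, d_theta=0.0, w_inh=0.0,
        neuron=NeuronParams(tau_M=20.0, t_refrac=t_refrac))


def _empty_stream(T_ms, width=2, height=2):
    return EventStream.empty(width, height, duration=T_ms)


class TestLifDynamics:
    def test_zero_input_stays_at_rest(self):
        cfg = _single_neuron_config(I=0.0)
        state = init_state(cfg, 4, 0)
        rec = simulate_pattern(state, _empty_stream(500), cfg)
        assert len(rec) == 0
        assert np.allclose(state.V, cfg.neuron.V_rest)

    @pytest.mark.parametrize("I", [0.8, 1.5, 3.0])
    def test_constant_drive_isi_matches_closed_form(self, I):
        cfg = _single_neuron_config(I=I)
        state = init_state(cfg, 4, 0)
        rec = simulate_pattern(state, _empty_stream(500), cfg)
        isis = np.diff(rec.times)
        expected = lif_isi_closed_form(cfg.neuron, I)
        assert len(isis) >= 3
        assert np.all(np.abs(isis - expected) <= cfg.dt + 1e-9)

    def test_halving_dt_moves_spikes_less_than_one_step(self):
        recs = {}
        for dt in (0.5, 0.25):
            cfg = _single_neuron_config(I=1.2, dt=dt, T=200.0)
            state = init_state(cfg, 4, 0)
            recs[dt] = simulate_pattern(state, _empty_stream(200), cfg).times
        n = min(len(recs[0.5]), len(recs[0.25]))
        assert n >= 2
        assert np.all(np.abs(recs[0.5][:n] - recs[0.25][:n]) <= 0.5 + 1e-9)

    def test_harder_driven_neuron_wins_and_suppresses_rival(self):
        # two neurons, neuron 0 weighted slightly higher on the same input
        cfg = NetworkConfig(mode="rate", N_e=2, A_xe=1.0, dA_xe=0.0,
                            current_gain=1.0, presentation_T=100.0, dt=0.5,
                            d_theta=0.0, w_inh=50.0, w_norm_total=None,
                            neuron=NeuronParams(tau_M=20.0, t_refrac=100.0),
                            kernels=SynapseKernels(tau_inh=50.0))
        state = init_state(cfg, 1, 0)
        state.W[:] = np.array([[1.0, 0.9]])
        stream = EventStream.from_arrays(
            np.arange(0, 100, 2), np.zeros(50, dtype=int),
            np.zeros(50, dtype=int), np.ones(50, dtype=int), 1, 1,
            duration=100)
        rec = simulate_pattern(state, stream, cfg)
        assert rec.neuron_ids[0] == 0
        assert 1 not in rec.neuron_ids  # rival held below threshold


class TestUnbinnedInputRejected:
    def test_microsecond_stream_raises(self):
        cfg = rate_mode_config(N_e=4)
        state = init_state(cfg, 4, 0)
        us_stream = EventStream.from_arrays([50_000], [0], [0], [1], 2, 2,
                                            duration=105_000)
        with pytest.raises(ValueError, match="bin_to_ms"):
            simulate_pattern(state, us_stream, cfg)


class TestReset:
    def test_reset_preserves_learned_state_only(self):
        cfg = rate_mode_config(N_e=8)
        state = init_state(cfg, 16, 0)
        state.theta[:] = 0.7
        W_before = state.W.copy()
        state.V[:] = -20.0
        state.x_pre[:] = 3.0
        reset_between_patterns(state, cfg)
        assert np.array_equal(state.W, W_before)
        assert np.all(state.theta == 0.7)
        assert np.all(state.V == cfg.neuron.V_rest)
        assert np.all(state.x_pre == 0.0)

    def test_no_spikes_on_empty_input_after_any_history(self):
        cfg = rate_mode_config(N_e=4)
        state = init_state(cfg, 4, 0)
        state.syn_d[:] = 50.0  # leftover drive
        reset_between_patterns(state, cfg)
        rec = simulate_pattern(state, _empty_stream(105), cfg)
        assert len(rec) == 0


class TestEscalation:
    def test_near_zero_weights_need_extra_passes(self):
        cfg = rate_mode_config(N_e=4, w_norm_total=None, A_xe=0.5,
                               current_gain=0.05)
        state = init_state(cfg, 4, 0)
        stream = EventStream.from_arrays(
            np.arange(100), np.tile([0, 1], 50)[:100] % 2,
            np.zeros(100, dtype=int), np.ones(100, dtype=int), 2, 2,
            duration=105)
        rec = present_with_escalation(state, stream, cfg)
        assert rec.n_passes > 1

    def test_escalation_deterministic(self):
        cfg = rate_mode_config(N_e=4, current_gain=0.05)
        stream = EventStream.from_arrays(
            np.arange(0, 105, 3), np.zeros(35, dtype=int),
            np.zeros(35, dtype=int), np.ones(35, dtype=int), 2, 2,
            duration=105)
        passes = []
        for _ in range(2):
            state = init_state(cfg, 4, 123)
            passes.append(present_with_escalation(state, stream, cfg).n_passes)
        assert passes[0] == passes[1]

    def test_cap_exceeded_raises_with_label(self):
        cfg = rate_mode_config(N_e=2, escalation_cap=3, A_xe=0.1, dA_xe=0.1,
                               w_norm_total=None)
        state = init_state(cfg, 4, 0)
        state.W *= 1e-9
        stream = EventStream.from_arrays([1], [0], [0], [1], 2, 2,
                                         duration=105, label=7)
        stream.label = 7
        with pytest.raises(EscalationError, match="label=7"):
            present_with_escalation(state, stream, cfg)

    def test_temporal_mode_rejects_escalation(self):
        cfg = temporal_mode_config(N_e=4)
        state = init_state(cfg, 4, 0)
        with pytest.raises(ValueError):
            present_with_escalation(state, _empty_stream(100), cfg)


class TestPeriodicResets:
    def test_tenth_of_presentation_schedule(self):
        cfg = temporal_mode_config(presentation_T=1450.0, N_e=4)
        sched = periodic_reset_schedule(cfg)
        assert sched == [145.0 * k for k in range(1, 10)]

    def test_fractional_step(self):
        cfg = temporal_mode_config(presentation_T=105.0, N_e=4)
        assert periodic_reset_schedule(cfg)[0] == pytest.approx(10.5)

    def test_rate_mode_has_no_resets(self):
        assert periodic_reset_schedule(rate_mode_config()) == []


class TestSom:
    def test_winner_scale_is_one(self):
        som = SomConfig(sigma0=2.0)
        assert som_scale(5, 5, 0.0, som, 25) == 1.0

    def test_scale_vanishes_with_distance(self):
        som = SomConfig(sigma0=1.0)
        near = som_scale(0, 1, 0.5, som, 100)
        far = som_scale(0, 99, 0.5, som, 100)
        assert far < near < 1.0
        assert far < 1e-6

    def test_sigma_halves_at_lambda_ln2(self):
        som = SomConfig(sigma0=3.0, lam=0.8)
        progress = som.lam * math.log(2.0)
        d2 = 4.0  # neuron two grid cells away
        base = som_scale(0, 2, 0.0, som, 25)
        later = som_scale(0, 2, progress, som, 25)
        # sigma -> sigma/2 quadruples the exponent
        assert math.log(later) == pytest.approx(4 * math.log(base), rel=1e-9)

    def test_non_square_grid_rejected(self):
        with pytest.raises(ValueError):
            som_scale(0, 1, 0.0, SomConfig(sigma0=1.0), 10)
        with pytest.raises(ValueError):
            temporal_mode_config(N_e=10, som=SomConfig(sigma0=1.0))


class TestLearnedStateInvariants:
    def test_weights_stay_in_bounds_after_training(self, rate_dataset_small):
        from tempocode.pipelines import (default_rate_run_config,
                                         prepare_dataset, run_rdstdp)
        train, test = rate_dataset_small
        cfg = default_rate_run_config(seed=0, N_e=16)
        res = run_rdstdp(prepare_dataset(train), prepare_dataset(test), cfg)
        assert 0.0 <= res.accuracy <= 1.0

    def test_theta_nondecreasing_up_to_negligible_decay(self):
        cfg = rate_mode_config(N_e=4)
        state = init_state(cfg, 4, 0)
        state.theta[:] = 1.0
        rec = simulate_pattern(state, _empty_stream(105), cfg)
        # decay over 105 ms at tau_theta = 1e7 ms: factor 1 - 1.05e-5
        assert np.all(state.theta >= 1.0 - 2e-5)
        assert np.all(state.theta <= 1.0)

    def test_theta_increments_on_spikes(self):
        cfg = _single_neuron_config(I=1.5)
        cfg = NetworkConfig(**{**cfg.__dict__, "d_theta": 0.3})
        state = init_state(cfg, 4, 0)
        rec = simulate_pattern(state, _empty_stream(500), cfg)
        assert state.theta[0] == pytest.approx(0.3 * len(rec), rel=1e-4)


class TestCheckpoint:
    def test_round_trip_preserves_learned_state(self, tmp_path):
        from tempocode.network import load_checkpoint, save_checkpoint
        cfg = temporal_mode_config(N_e=9, som=SomConfig(sigma0=0.75))
        state = init_state(cfg, 16, 5)
        state.theta[:] = np.arange(9) * 0.1
        path = tmp_path / "net.npz"
        save_checkpoint(state, cfg, path)
        back_state, back_cfg = load_checkpoint(path)
        assert np.array_equal(back_state.W, state.W)
        assert np.array_equal(back_state.theta, state.theta)
        assert back_cfg == cfg
        assert np.all(back_state.V == cfg.neuron.V_rest)
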