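"""Clock-driven two-layer winner-take-all spiking network.

Architecture: an input layer (one neuron per sensor pixel) projects all-to-all
with plastic weights ``W`` onto an excitatory layer of ``N_e`` current-based
LIF neurons.  Each excitatory neuron drives a dedicated inhibitory partner,
which in turn inhibits every *other* excitatory neuron — the net effect is
lateral inhibition, so the first neuron to fire suppresses its competitors.
The inhibitory layer is modelled as a deterministic one-step relay, since its
only role here is that lateral inhibition.

Membrane dynamics (exponential-Euler, exact for piecewise-constant current):

    dV/dt = (V_rest - V) / tau_M + I_syn

with ``I_syn`` in mV/ms.  Input spikes inject current through a
difference-of-exponentials kernel (gradual rise, gradual fall); inhibition
uses a single-exponential kernel (instant rise, gradual fall).  The firing
threshold is ``v_thresh + theta``: ``theta`` is a per-neuron homeostatic
offset incremented by ``d_theta`` at every spike and decaying with the very
large constant ``tau_theta`` (default 1e7 ms — negligible within a
presentation), which equalises firing rates across the layer over training.

Two presentation protocols:

* **rate** mode — long membrane constant, strong long-lived inhibition, and
  escalation: a silent presentation is repeated with the input current
  amplitude raised by ``dA_xe`` until at least one output spike occurs.  The
  intended regime is a single output spike toward the end of the window.
* **temporal** mode — membrane and trace constants a tenth of the
  presentation, state resets every tenth of the window, constant amplitude,
  and optionally a self-organising-map neighbourhood on weight updates; the
  output is a *sequence* of spikes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .events import EventStream
from .plasticity import TraceParams

__all__ = [
    "NeuronParams",
    "SynapseKernels",
    "SomConfig",
    "NetworkConfig",
    "NetworkState",
    "SpikeRecord",
    "EscalationError",
    "init_state",
    "normalize_input_weights",
    "save_checkpoint",
    "load_checkpoint",
    "simulate_pattern",
    "present_with_escalation",
    "reset_between_patterns",
    "periodic_reset_schedule",
    "som_scale",
    "rate_mode_config",
    "temporal_mode_config",
]


class EscalationError(RuntimeError):
    pass


@dataclass(frozen=True)
class NeuronParams:
    """Excitatory LIF constants (mV, ms)."""

    V_rest: float = -65.0
    v_thresh: float = -52.0
    V_reset: float = -65.0
    tau_M: float = 105.0
    t_refrac: float = 2.0

    def __post_init__(self) -> None:
        if not (self.V_reset <= self.V_rest < self.v_thresh):
            raise ValueError("require V_reset <= V_rest < v_thresh")
        if self.tau_M <= 0:
            raise ValueError("tau_M must be positive")


@dataclass(frozen=True)
class SynapseKernels:
    """Synaptic current kernels (ms).

    The input->excitatory kernel is a difference of exponentials normalised
    to unit peak; inhibition is a single exponential with instant rise.
    """

    tau_rise: float = 1.0
    tau_decay: float = 5.0
    tau_inh: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("require 0 < tau_rise < tau_decay")
        if self.tau_inh <= 0:
            raise ValueError("tau_inh must be positive")

    @property
    def peak_norm(self) -> float:
        """Scale making the input kernel's peak equal 1."""
        tr, td = self.tau_rise, self.tau_decay
        t_pk = tr * td / (td - tr) * math.log(td / tr)
        return 1.0 / (math.exp(-t_pk / td) - math.exp(-t_pk / tr))


@dataclass(frozen=True)
class SomConfig:
    """Self-organising-map neighbourhood on a sqrt(N_e) x sqrt(N_e) grid.

    The neighbourhood width shrinks as sigma0 * exp(-progress / lam) with
    training progress in [0, 1].
    """

    sigma0: float
    lam: float = 0.5


@dataclass(frozen=True)
class NetworkConfig:
    mode: str = "rate"                      # "rate" | "temporal"
    N_e: int = 100
    A_xe: float = 5.0                       # input EPSC amplitude, nA
    dA_xe: float = 1.0                      # escalation increment, nA
    current_gain: float = 0.0012            # mV/ms of drive per nA per unit weighted kernel
    d_theta: float = 0.2                    # threshold increment, mV
    tau_theta: float = 1.0e7                # theta decay constant, ms
    w_inh: float = 4.0                      # inhibitory current amplitude, mV/ms
    presentation_T: float = 105.0           # ms
    dt: float = 0.5                         # ms
    neuron: NeuronParams = field(default_factory=NeuronParams)
    kernels: SynapseKernels = field(default_factory=SynapseKernels)
    som: SomConfig | None = None
    w_init_max: float = 0.3
    w_norm_total: float | None = 40.0       # per-neuron input weight budget (L1)
    bias_current: float = 0.0               # constant drive (mV/ms), test hook
    escalation_cap: int = 50

    def __post_init__(self) -> None:
        if self.mode not in ("rate", "temporal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.N_e < 1 or self.dt <= 0:
            raise ValueError("need N_e >= 1 and dt > 0")
        n_steps = self.presentation_T / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("presentation_T must be a multiple of dt")
        if self.som is not None:
            side = math.isqrt(self.N_e)
            if side * side != self.N_e:
                raise ValueError(
                    "SOM neighbourhood requires a square N_e grid")

    @property
    def n_steps(self) -> int:
        return round(self.presentation_T / self.dt)


def rate_mode_config(**overrides) -> NetworkConfig:
    """Rate-regime defaults: tau_M ~ the presentation, strong inhibition."""
    base = dict(mode="rate", presentation_T=105.0, A_xe=2.0, dA_xe=0.5,
                w_inh=4.0,
                neuron=NeuronParams(tau_M=1000.0, t_refrac=30.0),
                kernels=SynapseKernels(tau_inh=30.0))
    base.update(overrides)
    return NetworkConfig(**base)


def temporal_mode_config(presentation_T: float = 100.0,
                         **overrides) -> NetworkConfig:
    """Temporal-regime defaults: tenth-of-presentation constants, resets."""
    base = dict(mode="temporal", presentation_T=presentation_T,
                A_xe=90.0, dA_xe=0.0, w_inh=3.0,
                neuron=NeuronParams(tau_M=presentation_T / 10.0,
                                    t_refrac=2.0),
                kernels=SynapseKernels(tau_inh=5.0))
    base.update(overrides)
    return NetworkConfig(**base)


@dataclass
class NetworkState:
    """Learned state (W, theta) plus the transient dynamic state."""

    W: np.ndarray            # (n_inputs, N_e), each weight in [0, w_max]
    theta: np.ndarray        # (N_e,) adaptive threshold offsets, mV
    V: np.ndarray            # (N_e,) membrane potentials
    refrac_until: np.ndarray  # (N_e,) absolute end of refractory period, ms
    syn_d: np.ndarray        # (n_inputs,) input kernel decay trace
    syn_r: np.ndarray        # (n_inputs,) input kernel rise trace
    inh: np.ndarray          # (N_e,) inhibitory current, mV/ms
    x_pre: np.ndarray        # (n_inputs,) presynaptic STDP trace

    @property
    def n_inputs(self) -> int:
        return self.W.shape[0]

    @property
    def N_e(self) -> int:
        return self.W.shape[1]


def init_state(config: NetworkConfig, n_inputs: int,
               rng: np.random.Generator | int = 0) -> NetworkState:
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    W = rng.uniform(0.0, config.w_init_max, size=(n_inputs, config.N_e))
    if config.w_norm_total is not None:
        normalize_input_weights(W, np.arange(config.N_e),
                                config.w_norm_total)
    return NetworkState(
        W=W,
        theta=np.zeros(config.N_e),
        V=np.full(config.N_e, config.neuron.V_rest),
        refrac_until=np.zeros(config.N_e),
        syn_d=np.zeros(n_inputs),
        syn_r=np.zeros(n_inputs),
        inh=np.zeros(config.N_e),
        x_pre=np.zeros(n_inputs),
    )


def normalize_input_weights(W: np.ndarray, cols: np.ndarray, total: float,
                            w_max: float | None = None) -> None:
    """Divisive normalisation: rescale each column to the L1 budget ``total``.

    Keeping every excitatory neuron's summed input weight constant makes the
    competition depend on how well a pattern *matches* a neuron's weight
    profile rather than on its raw weight mass.  Applied at initialisation
    and after every plastic update.
    """
    for j in np.atleast_1d(cols):
        s = W[:, j].sum()
        if s > 0:
            W[:, j] *= total / s
            if w_max is not None:
                np.clip(W[:, j], 0.0, w_max, out=W[:, j])


def reset_between_patterns(state: NetworkState,
                           config: NetworkConfig) -> NetworkState:
    """Zero/rest all transient state; W and theta are left untouched."""
    state.V.fill(config.neuron.V_rest)
    state.refrac_until.fill(0.0)
    state.syn_d.fill(0.0)
    state.syn_r.fill(0.0)
    state.inh.fill(0.0)
    state.x_pre.fill(0.0)
    return state


def periodic_reset_schedule(config: NetworkConfig) -> list[float]:
    """Interior reset times for temporal mode: k, 2k, ... with k = T/10."""
    if config.mode != "temporal":
        return []
    k = config.presentation_T / 10.0
    return [k * i for i in range(1, 10)]


def som_scale(winner: int, other: int, progress: float,
              som: SomConfig, N_e: int) -> float:
    """Gaussian neighbourhood multiplier on the SOM grid; 1 for the winner."""
    side = math.isqrt(N_e)
    if side * side != N_e:
        raise ValueError("SOM requires square N_e")
    wy, wx = divmod(winner, side)
    oy, ox = divmod(other, side)
    d2 = (wy - oy) ** 2 + (wx - ox) ** 2
    sigma = som.sigma0 * math.exp(-progress / som.lam)
    return math.exp(-d2 / (2.0 * sigma * sigma))


def _som_scales(winner: int, progress: float, som: SomConfig,
                N_e: int) -> np.ndarray:
    side = math.isqrt(N_e)
    ids = np.arange(N_e)
    d2 = (ids // side - winner // side) ** 2 + (ids % side - winner % side) ** 2
    sigma = som.sigma0 * math.exp(-progress / som.lam)
    return np.exp(-d2 / (2.0 * sigma * sigma))


@dataclass
class SpikeRecord:
    """Output spikes of one presentation: (neuron id, time in ms) pairs."""

    neuron_ids: np.ndarray
    times: np.ndarray
    presentation_T: float
    n_passes: int = 1           # escalation passes used (rate mode)

    def __len__(self) -> int:
        return len(self.neuron_ids)

    def first_spike(self) -> tuple[int, float]:
        if not len(self.neuron_ids):
            raise ValueError("record has no spikes")
        return int(self.neuron_ids[0]), float(self.times[0])

    def counts(self, N_e: int) -> np.ndarray:
        c = np.zeros(N_e, dtype=np.int64)
        np.add.at(c, self.neuron_ids, 1)
        return c


def save_checkpoint(state: NetworkState, config: NetworkConfig, path) -> None:
    """Archive the learned state (W, theta) with its network config."""
    import dataclasses
    import json

    np.savez_compressed(path, W=state.W, theta=state.theta,
                        config=np.frombuffer(
                            json.dumps(dataclasses.asdict(config)).encode(),
                            dtype=np.uint8))


def load_checkpoint(path) -> tuple[NetworkState, NetworkConfig]:
    """Restore a checkpoint; transient dynamic state comes back at rest."""
    import json

    with np.load(path) as npz:
        raw = json.loads(bytes(npz["config"]).decode())
        som = SomConfig(**raw.pop("som")) if raw.get("som") else None
        raw.pop("som", None)
        config = NetworkConfig(neuron=NeuronParams(**raw.pop("neuron")),
                               kernels=SynapseKernels(**raw.pop("kernels")),
                               som=som, **raw)
        W = npz["W"]
        state = init_state(config, W.shape[0], 0)
        state.W[:] = W
        state.theta[:] = npz["theta"]
    reset_between_patterns(state, config)
    return state, config


PlasticityHook = Callable[[NetworkState, np.ndarray, float], None]
# signature: hook(state, spiking neuron ids, time ms) -> None (mutates state.W)


def _binned_counts(stream: EventStream, config: NetworkConfig,
                   n_inputs: int) -> np.ndarray:
    """Per-simulation-step input spike counts, (n_steps, n_inputs)."""
    if stream.duration > config.presentation_T + 1e-9:
        raise ValueError(
            f"stream duration {stream.duration} exceeds the presentation "
            f"window {config.presentation_T} ms — bin_to_ms() the stream "
            "and window it first")
    counts = np.zeros((config.n_steps, n_inputs))
    if len(stream):
        steps = np.minimum((stream.t / config.dt).astype(np.int64),
                           config.n_steps - 1)
        np.add.at(counts, (steps, stream.pixel_index()), 1.0)
    return counts


def simulate_pattern(state: NetworkState, stream: EventStream,
                     config: NetworkConfig,
                     plasticity: PlasticityHook | None = None,
                     trace: TraceParams | None = None,
                     A_eff: float | None = None,
                     freeze_theta: bool = False) -> SpikeRecord:
    """Integrate one pattern presentation at step ``dt``.

    ``stream`` must be ms-binned (timestamps in ms ticks) and fit within the
    presentation window.  ``trace`` enables online maintenance of the
    presynaptic STDP trace ``state.x_pre``; ``plasticity`` is invoked at each
    output spike with the spiking neuron ids.  ``A_eff`` overrides the input
    amplitude (used by the escalation protocol).  ``freeze_theta`` disables
    homeostatic threshold adaptation — used at labeling/evaluation time so
    the learnt competition is probed, not altered.
    """
    counts = _binned_counts(stream, config, state.n_inputs)
    dt = config.dt
    nrn, ker = config.neuron, config.kernels
    decay_d = math.exp(-dt / ker.tau_decay)
    decay_r = math.exp(-dt / ker.tau_rise)
    decay_inh = math.exp(-dt / ker.tau_inh)
    decay_theta = math.exp(-dt / config.tau_theta)
    decay_v = math.exp(-dt / nrn.tau_M)
    if trace is not None:
        decay_x = (1.0 if math.isinf(trace.tau_xpre)
                   else math.exp(-dt / trace.tau_xpre))
    A = config.A_xe if A_eff is None else A_eff
    k_norm = ker.peak_norm
    resets = periodic_reset_schedule(config)
    reset_steps = {round(r / dt) for r in resets if 0 < r < config.presentation_T}

    spike_ids: list[int] = []
    spike_times: list[float] = []
    for step in range(config.n_steps):
        t = step * dt
        if step in reset_steps:
            # tenth-of-presentation reset: voltages, currents and synaptic
            # traces go back to rest; W and theta persist
            state.V.fill(nrn.V_rest)
            state.syn_d.fill(0.0)
            state.syn_r.fill(0.0)
            state.inh.fill(0.0)
            state.x_pre.fill(0.0)
        c = counts[step]
        if c.any():
            state.syn_d += c
            state.syn_r += c
            if trace is not None:
                state.x_pre += c * trace.dx_pre
        kernel = k_norm * (state.syn_d - state.syn_r)
        I = (config.current_gain * A * (state.W.T @ kernel)
             - state.inh + config.bias_current)
        active = state.refrac_until <= t + 1e-12
        V_inf = nrn.V_rest + I * nrn.tau_M
        state.V[active] = V_inf[active] + (state.V[active] - V_inf[active]) * decay_v
        fired = np.nonzero(active & (state.V >= nrn.v_thresh + state.theta))[0]
        if fired.size > 1:
            # WTA discretisation: of the neurons crossing within one step,
            # the one with the largest threshold overshoot fired first
            over = state.V[fired] - (nrn.v_thresh + state.theta[fired])
            keep = fired[int(np.argmax(over))]
            state.V[fired] = np.minimum(state.V[fired],
                                        nrn.v_thresh + state.theta[fired]
                                        - 1e-9)
            fired = np.array([keep])
        if fired.size:
            state.V[fired] = nrn.V_reset
            state.refrac_until[fired] = t + nrn.t_refrac
            if not freeze_theta:
                state.theta[fired] += config.d_theta
            # each spiker inhibits every excitatory neuron except itself
            state.inh += config.w_inh * fired.size
            state.inh[fired] -= config.w_inh
            for j in fired:
                spike_ids.append(int(j))
                spike_times.append(t)
            if plasticity is not None:
                plasticity(state, fired, t)
        state.syn_d *= decay_d
        state.syn_r *= decay_r
        state.inh *= decay_inh
        state.theta *= decay_theta
        if trace is not None:
            state.x_pre *= decay_x
    return SpikeRecord(np.array(spike_ids, dtype=np.int64),
                       np.array(spike_times), config.presentation_T)


def present_with_escalation(state: NetworkState, stream: EventStream,
                            config: NetworkConfig,
                            plasticity: PlasticityHook | None = None,
                            trace: TraceParams | None = None,
                            freeze_theta: bool = False) -> SpikeRecord:
    """Rate-mode presentation: raise A_xe by dA_xe after silent passes.

    The effective amplitude resets to the baseline for the next pattern.
    Raises :class:`EscalationError` after ``escalation_cap`` silent passes.
    """
    if config.mode != "rate":
        raise ValueError("escalation protocol applies to rate mode only")
    for attempt in range(config.escalation_cap + 1):
        reset_between_patterns(state, config)
        A_eff = config.A_xe + attempt * config.dA_xe
        record = simulate_pattern(state, stream, config, plasticity,
                                  trace, A_eff=A_eff,
                                  freeze_theta=freeze_theta)
        if len(record):
            record.n_passes = attempt + 1
            return record
    raise EscalationError(
        f"no output spike after {config.escalation_cap} escalation passes "
        f"(pattern label={stream.label})")
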