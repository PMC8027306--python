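"""End-to-end training/evaluation pipelines and the grid-search protocol.

Four pipelines share one skeleton — unsupervised STDP training of the WTA
layer, then a readout evaluated on a held-out split:

* ``run_rdstdp``       — rate-regime trace STDP (long trace constant, single
                         late output spike, escalation) + rate readout.
* ``run_stdp_tempotron``— temporal regime (tenth-of-presentation constants,
                         periodic resets, SOM neighbourhood, constant
                         amplitude) + supervised tempotron over the output
                         spike sequences.
* ``run_fixed_tstar``  — phase A: an RD-STDP run recording first
                         postsynaptic spike times; phase B: training from
                         scratch with the presynaptic trace frozen at the
                         mean spike time t*.
* ``run_psth``         — the population-rate rule: a learning kernel
                         h = a*H + b fitted to the training PSTH, updates at
                         the end of each presentation.

The design-space-exploration protocol (``dse1``/``dse2``) and the six-member
majority-vote ensemble close the module.  Class labels are never readable by
the unsupervised stages: training views carry a guard object that raises on
any attempt to use the label.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Callable

import numpy as np
import pandas as pd

from .events import EventStream, LabeledDataset, bin_to_ms
from .network import (NetworkConfig, NetworkState, SomConfig, SpikeRecord,
                      _som_scales, init_state, normalize_input_weights,
                      present_with_escalation,
                      rate_mode_config, reset_between_patterns,
                      simulate_pattern, temporal_mode_config)
from .plasticity import (FixedTimeSpec, TraceParams, apply_update,
                         compute_psth, fit_scale_bias, fixed_time_update,
                         psth_trace_per_pixel, psth_update, stdp_update)
from .readout import (TempotronModel, assign_labels, classify_rate,
                      classify_sequence, train_tempotron)

__all__ = [
    "RunConfig",
    "RunResult",
    "DseGrid",
    "LabelAccessError",
    "prepare_dataset",
    "run_rdstdp",
    "run_stdp_tempotron",
    "run_fixed_tstar",
    "run_psth",
    "run_pipeline",
    "dse1",
    "dse2",
    "ensemble_majority",
    "evaluate_and_report",
    "NMNIST_DSE_GRID",
    "GESTURE_DSE_GRID",
    "DSE2_SIZES",
]


class LabelAccessError(RuntimeError):
    """An unsupervised stage tried to read a class label."""


class _GuardedLabel:
    """Stand-in label that raises on any attempt to use it."""

    def _refuse(self, *args, **kwargs):
        raise LabelAccessError(
            "class labels are not accessible during unsupervised training")

    __int__ = __index__ = __eq__ = __ne__ = __hash__ = _refuse  # type: ignore
    __repr__ = __str__ = _refuse


def _unsupervised_view(ds: LabeledDataset) -> list[EventStream]:
    """Streams with labels replaced by a guard that raises on access."""
    guard = _GuardedLabel()
    out = []
    for s in ds.streams:
        view = EventStream.__new__(EventStream)
        view.t, view.x, view.y, view.p = s.t, s.x, s.y, s.p
        view.width, view.height, view.duration = s.width, s.height, s.duration
        view.label = guard
        out.append(view)
    return out


def prepare_dataset(ds: LabeledDataset) -> LabeledDataset:
    """Millisecond-bin every stream (presentation input resolution)."""
    return LabeledDataset([bin_to_ms(s) for s in ds.streams],
                          ds.labels.copy())


@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    pipeline: str                       # rdstdp | stdp_tempotron | fixed_tstar | psth
    network: NetworkConfig
    trace: TraceParams
    epochs: int = 1
    seed: int = 0
    tempotron_lam: float = 0.02
    tempotron_epochs: int = 30
    psth_kappa: float = 1.1
    psth_calibration_n: int = 100
    calibrate_A: bool = True     # ballpark-amplitude search before training

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=repr).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunResult:
    """Outcome of a pipeline run: accuracies, confusion, provenance."""

    pipeline: str
    accuracy: float
    confusion: np.ndarray
    n_test: int
    escalation_passes: int           # extra presentation passes over the run
    fallback_count: int              # test patterns decided by the fallback
    config_hash: str
    seed: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pipeline": self.pipeline,
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "n_test": self.n_test,
            "escalation_passes": self.escalation_passes,
            "fallback_count": self.fallback_count,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "extras": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in self.extras.items()},
        }


def _trace_hook(params: TraceParams,
                som: SomConfig | None = None,
                N_e: int = 0,
                progress: Callable[[], float] | None = None,
                norm_total: float | None = None):
    """Online trace-STDP hook; optional SOM neighbourhood co-training."""

    def hook(state: NetworkState, fired: np.ndarray, t: float) -> None:
        for j in fired:
            if som is None:
                cols = np.array([j])
                scales = np.ones(1)
            else:
                scales = _som_scales(int(j), progress(), som, N_e)
                cols = np.nonzero(scales > 1e-4)[0]
                scales = scales[cols]
            for m, sc in zip(cols, scales):
                dw_m = stdp_update(state.W[:, m], state.x_pre, params)
                apply_update(state.W[:, m], sc * dw_m, params.w_max)
            if norm_total is not None:
                normalize_input_weights(state.W, cols, norm_total,
                                        params.w_max)
    return hook


def calibrate_baseline_amplitude(streams: list[EventStream],
                                 network: NetworkConfig,
                                 state: NetworkState,
                                 n_probe: int = 8) -> NetworkConfig:
    """Ballpark search for the input amplitude, before any learning.

    The escalation protocol can only raise the drive, so a baseline that is
    too strong makes the output spike early in the window instead of toward
    its end.  This probes a few training patterns with the initial weights
    and sets the baseline to the smallest multiple of ``dA_xe`` at which the
    median probe pattern barely spikes — escalation then supplies the rest
    per pattern, and the single output spike lands late, where the whole
    pattern has been integrated.
    """
    if network.dA_xe <= 0:
        return network
    probes = streams[:: max(len(streams) // n_probe, 1)][:n_probe]
    minima = []
    for s in probes:
        for k in range(1, 4 * network.escalation_cap):
            reset_between_patterns(state, network)
            rec = simulate_pattern(state, s, network, None, None,
                                   A_eff=k * network.dA_xe,
                                   freeze_theta=True)
            if len(rec):
                minima.append(k)
                break
    reset_between_patterns(state, network)
    if not minima:
        return network
    k_base = max(int(np.median(minima)) - 1, 1)
    return replace(network, A_xe=k_base * network.dA_xe)


def _present_all(state: NetworkState, streams: list[EventStream],
                 cfg: NetworkConfig, trace: TraceParams | None,
                 hook=None, escalate: bool | None = None,
                 freeze_theta: bool = False
                 ) -> tuple[list[SpikeRecord], int]:
    """Present every stream; returns records and total extra passes."""
    if escalate is None:
        escalate = cfg.mode == "rate"
    records = []
    extra = 0
    for s in streams:
        if escalate:
            rec = present_with_escalation(state, s, cfg, hook, trace,
                                          freeze_theta=freeze_theta)
            extra += rec.n_passes - 1
        else:
            reset_between_patterns(state, cfg)
            rec = simulate_pattern(state, s, cfg, hook, trace,
                                   freeze_theta=freeze_theta)
        records.append(rec)
    return records, extra


def _rate_readout(state: NetworkState, cfg: NetworkConfig,
                  train: LabeledDataset, test: LabeledDataset
                  ) -> tuple[float, np.ndarray, int, int, np.ndarray]:
    """Label neurons on the training set, then rate-classify the test set.

    Homeostatic threshold adaptation is frozen here: evaluation probes the
    learnt competition without altering it.
    """
    train_records, extra1 = _present_all(
        state, train.streams, cfg, trace=None, hook=None, freeze_theta=True)
    labels = assign_labels(train_records, train.labels, cfg.N_e)
    test_records, extra2 = _present_all(
        state, test.streams, cfg, trace=None, hook=None, freeze_theta=True)
    K = max(train.n_classes, test.n_classes)
    confusion = np.zeros((K, K), dtype=np.int64)
    fallbacks = 0
    preds = np.zeros(len(test), dtype=np.int64)
    for i, (rec, y) in enumerate(zip(test_records, test.labels)):
        pred, fb = classify_rate(labels, rec)
        fallbacks += fb
        confusion[y, pred] += 1
        preds[i] = pred
    acc = float(np.trace(confusion) / len(test))
    return acc, confusion, extra1 + extra2, fallbacks, preds


def _training_order(n: int, epochs: int,
                    rng: np.random.Generator) -> list[int]:
    order: list[int] = []
    for _ in range(epochs):
        order.extend(rng.permutation(n).tolist())
    return order


def run_rdstdp(train: LabeledDataset, test: LabeledDataset,
               cfg: RunConfig,
               record_spike_times: bool = False) -> RunResult:
    """Rate-regime pipeline: unsupervised trace STDP + rate readout."""
    if cfg.network.mode != "rate":
        raise ValueError("run_rdstdp needs a rate-mode network config")
    rng = np.random.default_rng(cfg.seed)
    n_inputs = train.width * train.height
    state = init_state(cfg.network, n_inputs, rng)
    streams = _unsupervised_view(train)
    net = (calibrate_baseline_amplitude(streams, cfg.network, state)
           if cfg.calibrate_A else cfg.network)
    hook = _trace_hook(cfg.trace, norm_total=net.w_norm_total)
    extra = 0
    first_spike_times: list[float] = []
    for i in _training_order(len(streams), cfg.epochs, rng):
        rec = present_with_escalation(state, streams[i], net,
                                      hook, cfg.trace)
        extra += rec.n_passes - 1
        if record_spike_times:
            first_spike_times.append(rec.first_spike()[1])
    acc, confusion, extra2, fallbacks, preds = _rate_readout(
        state, net, train, test)
    extras: dict = {"assigned_neurons": int((state.theta > 0).sum()),
                    "predictions": preds}
    if record_spike_times:
        extras["train_first_spike_times"] = np.array(first_spike_times)
        extras["state"] = state
    return RunResult("rdstdp", acc, confusion, len(test), extra + extra2,
                     fallbacks, cfg.config_hash(), cfg.seed, extras)


def run_stdp_tempotron(train: LabeledDataset, test: LabeledDataset,
                       cfg: RunConfig) -> RunResult:
    """Temporal pipeline: short-trace STDP + SOM, tempotron over sequences."""
    if cfg.network.mode != "temporal":
        raise ValueError("run_stdp_tempotron needs a temporal-mode config")
    rng = np.random.default_rng(cfg.seed)
    n_inputs = train.width * train.height
    state = init_state(cfg.network, n_inputs, rng)
    streams = _unsupervised_view(train)
    order = _training_order(len(streams), cfg.epochs, rng)
    n_total = len(order)
    counter = {"i": 0}
    hook = _trace_hook(cfg.trace, som=cfg.network.som, N_e=cfg.network.N_e,
                       progress=lambda: counter["i"] / max(n_total, 1),
                       norm_total=cfg.network.w_norm_total)
    for i in order:
        reset_between_patterns(state, cfg.network)
        simulate_pattern(state, streams[i], cfg.network, hook, cfg.trace)
        counter["i"] += 1
    # sequences of the trained network, plasticity off
    train_records, _ = _present_all(state, train.streams, cfg.network,
                                    trace=None, hook=None, escalate=False,
                                    freeze_theta=True)
    test_records, _ = _present_all(state, test.streams, cfg.network,
                                   trace=None, hook=None, escalate=False,
                                   freeze_theta=True)
    K = max(train.n_classes, test.n_classes)
    model = TempotronModel(
        n_afferents=cfg.network.N_e, n_classes=K,
        tau=cfg.network.presentation_T / 10.0,
        lam=cfg.tempotron_lam, max_epochs=cfg.tempotron_epochs)
    train_tempotron(model, train_records, train.labels, seed=cfg.seed)
    confusion = np.zeros((K, K), dtype=np.int64)
    empties = 0
    preds = np.zeros(len(test), dtype=np.int64)
    for i, (rec, y) in enumerate(zip(test_records, test.labels)):
        empties += not len(rec)
        preds[i] = classify_sequence(model, rec)
        confusion[y, preds[i]] += 1
    acc = float(np.trace(confusion) / len(test))
    return RunResult("stdp_tempotron", acc, confusion, len(test), 0, empties,
                     cfg.config_hash(), cfg.seed,
                     {"tempotron_converged": bool(model.converged),
                      "predictions": preds})


def _trace_at_tstar(stream: EventStream, t_star: float, p: TraceParams,
                    n_inputs: int) -> np.ndarray:
    """Per-pixel presynaptic trace at the fixed time t* (vectorised)."""
    x = np.zeros(n_inputs)
    if len(stream):
        mask = stream.t <= t_star
        decay = (np.ones(mask.sum()) if math.isinf(p.tau_xpre)
                 else np.exp(-(t_star - stream.t[mask]) / p.tau_xpre))
        np.add.at(x, stream.pixel_index()[mask], p.dx_pre * decay)
    return x


def run_fixed_tstar(train: LabeledDataset, test: LabeledDataset,
                    cfg: RunConfig) -> RunResult:
    """Two-phase pipeline testing insensitivity to postsynaptic spike time.

    Phase A is a full rate-regime run that records the first postsynaptic
    spike time of every training presentation; t* is their mean.  Phase B
    retrains from fresh initial weights, with the winner still chosen by the
    real first-spike competition but the presynaptic trace evaluated at t*.
    """
    if cfg.network.mode != "rate":
        raise ValueError("run_fixed_tstar needs a rate-mode network config")
    phase_a = run_rdstdp(train, test, cfg, record_spike_times=True)
    t_star = float(np.mean(phase_a.extras["train_first_spike_times"]))
    spec = FixedTimeSpec(t_star)

    rng = np.random.default_rng(cfg.seed + 1)  # independent fresh weights
    n_inputs = train.width * train.height
    state = init_state(cfg.network, n_inputs, rng)
    streams = _unsupervised_view(train)
    net = (calibrate_baseline_amplitude(streams, cfg.network, state)
           if cfg.calibrate_A else cfg.network)
    extra = 0
    for i in _training_order(len(streams), cfg.epochs, rng):
        rec = present_with_escalation(state, streams[i], net,
                                      None, None)
        extra += rec.n_passes - 1
        winner, _ = rec.first_spike()
        x_star = _trace_at_tstar(streams[i], spec.t_star, cfg.trace, n_inputs)
        dw = fixed_time_update(state.W[:, winner], x_star, cfg.trace)
        apply_update(state.W[:, winner], dw, cfg.trace.w_max)
        if net.w_norm_total is not None:
            normalize_input_weights(state.W, np.array([winner]),
                                    net.w_norm_total, cfg.trace.w_max)
    acc, confusion, extra2, fallbacks, preds = _rate_readout(
        state, net, train, test)
    return RunResult("fixed_tstar", acc, confusion, len(test), extra + extra2,
                     fallbacks, cfg.config_hash(), cfg.seed,
                     {"t_star": t_star, "predictions": preds,
                      "phase_a_accuracy": phase_a.accuracy})


def run_psth(train: LabeledDataset, test: LabeledDataset,
             cfg: RunConfig) -> RunResult:
    """Population-rate pipeline: PSTH-derived kernel, end-of-window updates."""
    if cfg.network.mode != "rate":
        raise ValueError("run_psth needs a rate-mode network config")
    rng = np.random.default_rng(cfg.seed)
    n_inputs = train.width * train.height
    T = cfg.network.presentation_T
    streams = _unsupervised_view(train)

    H_prime, H = compute_psth(train, dt_bin=1.0, T_ms=T)
    n_bins = len(H)
    # calibration batch: first patterns, per-pixel per-bin counts
    n_cal = min(cfg.psth_calibration_n, len(streams))
    cal_counts = []
    for s in streams[:n_cal]:
        c = np.zeros((n_inputs, n_bins))
        if len(s):
            bins = np.minimum(s.t.astype(np.int64), n_bins - 1)
            np.add.at(c, (s.pixel_index(), bins), 1.0)
        cal_counts.append(c)
    # reference: mean |dw| of the trace rule at the midpoint weight
    w0 = 0.5 * cfg.trace.w_max
    ref_scale = (cfg.trace.w_max - w0) ** cfg.trace.mu
    ref_mags = []
    for s in streams[:n_cal]:
        x_end = _trace_at_tstar(s, T, cfg.trace, n_inputs)
        ref_mags.append(np.abs(
            cfg.trace.eta * (x_end - cfg.trace.x_tar) * ref_scale).mean())
    curve = fit_scale_bias(H, float(np.mean(ref_mags)), cal_counts,
                           dt_bin=1.0, kappa=cfg.psth_kappa, p=cfg.trace)
    curve.N_patterns = len(train)

    state = init_state(cfg.network, n_inputs, rng)
    net = (calibrate_baseline_amplitude(streams, cfg.network, state)
           if cfg.calibrate_A else cfg.network)
    extra = 0
    for i in _training_order(len(streams), cfg.epochs, rng):
        rec = present_with_escalation(state, streams[i], net,
                                      None, None)
        extra += rec.n_passes - 1
        winner, _ = rec.first_spike()
        x_pre = psth_trace_per_pixel(streams[i], curve, cfg.trace.x_tar,
                                     n_inputs)
        dw = psth_update(state.W[:, winner], x_pre, cfg.trace)
        apply_update(state.W[:, winner], dw, cfg.trace.w_max)
        if net.w_norm_total is not None:
            normalize_input_weights(state.W, np.array([winner]),
                                    net.w_norm_total, cfg.trace.w_max)
    acc, confusion, extra2, fallbacks, preds = _rate_readout(
        state, net, train, test)
    return RunResult("psth", acc, confusion, len(test), extra + extra2,
                     fallbacks, cfg.config_hash(), cfg.seed,
                     {"psth_H": H, "psth_a": curve.a, "psth_b": curve.b,
                      "ltd_area": curve.ltd_area(),
                      "ltp_area": curve.ltp_area(),
                      "predictions": preds})


_PIPELINES = {
    "rdstdp": run_rdstdp,
    "stdp_tempotron": run_stdp_tempotron,
    "fixed_tstar": run_fixed_tstar,
    "psth": run_psth,
}


def run_pipeline(train: LabeledDataset, test: LabeledDataset,
                 cfg: RunConfig) -> RunResult:
    try:
        fn = _PIPELINES[cfg.pipeline]
    except KeyError:
        raise ValueError(f"unknown pipeline {cfg.pipeline!r}") from None
    return fn(train, test, cfg)


# ---------------------------------------------------------------------------
# Design-space exploration

@dataclass(frozen=True)
class DseGrid:
    """DSE1 axes: learning rate, threshold step, (temporal only) amplitude."""

    eta: tuple[float, ...] = (0.0005, 0.005, 0.05, 0.5)
    d_theta: tuple[float, ...] = (1.0, 0.1, 0.01)       # mV
    A_xe: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)      # nA
    sizes: tuple[int, ...] = (49, 225, 400, 576, 729, 900)

    def __post_init__(self) -> None:
        if not (self.eta and self.d_theta and self.A_xe and self.sizes):
            raise ValueError("grid axes must be non-empty")

    def cells(self, pipeline: str) -> list[dict]:
        """Cartesian product of the axes relevant to the pipeline."""
        if pipeline == "stdp_tempotron":
            return [{"eta": e, "d_theta": d, "A_xe": a}
                    for e, d, a in product(self.eta, self.d_theta, self.A_xe)]
        return [{"eta": e, "d_theta": d}
                for e, d in product(self.eta, self.d_theta)]


NMNIST_DSE_GRID = DseGrid(A_xe=(1.0, 3.0, 5.0, 7.0))
GESTURE_DSE_GRID = DseGrid(A_xe=(0.1, 0.3, 0.5, 0.7))
DSE2_SIZES = (49, 225, 400, 576, 729, 900)


def _apply_cell(cfg: RunConfig, cell: dict) -> RunConfig:
    network = cfg.network
    if "d_theta" in cell:
        network = replace(network, d_theta=cell["d_theta"])
    if "A_xe" in cell:
        network = replace(network, A_xe=cell["A_xe"])
    trace = cfg.trace
    if "eta" in cell:
        trace = replace(trace, eta=cell["eta"])
    return replace(cfg, network=network, trace=trace)


def dse1(grid: DseGrid, base_configs: dict[str, RunConfig],
         train: LabeledDataset, test: LabeledDataset,
         runner: Callable[[LabeledDataset, LabeledDataset, RunConfig],
                          RunResult] = run_pipeline,
         ) -> tuple[pd.DataFrame, dict[str, RunConfig]]:
    """Grid search over (eta, d_theta[, A_xe]) at fixed network size.

    ``base_configs`` maps pipeline id -> its base RunConfig (network size per
    case).  Returns the full result table and the best config per pipeline
    (max test accuracy).
    """
    rows = []
    best: dict[str, RunConfig] = {}
    best_acc: dict[str, float] = {}
    for pipeline, base in base_configs.items():
        for cell in grid.cells(pipeline):
            cfg = _apply_cell(base, cell)
            result = runner(train, test, cfg)
            rows.append({"pipeline": pipeline, **cell,
                         "N_e": cfg.network.N_e,
                         "accuracy": result.accuracy,
                         "config_hash": cfg.config_hash(),
                         "seed": cfg.seed})
            if result.accuracy > best_acc.get(pipeline, -1.0):
                best_acc[pipeline] = result.accuracy
                best[pipeline] = cfg
    return pd.DataFrame(rows), best


def scale_for_size(cfg: RunConfig, N_e: int, N_ref: int) -> RunConfig:
    """Rescale eta and d_theta linearly with network size.

    Each neuron wins roughly 1/N_e of the presentations, so scaling both
    learning rate and threshold step by N_e/N_ref keeps the expected
    per-neuron cumulative update size-invariant.
    """
    factor = N_e / N_ref
    network = replace(cfg.network, N_e=N_e,
                      d_theta=cfg.network.d_theta * factor)
    trace = replace(cfg.trace, eta=min(cfg.trace.eta * factor, 1.0))
    return replace(cfg, network=network, trace=trace)


def dse2(best_cfg: RunConfig, sizes: tuple[int, ...],
         train: LabeledDataset, test: LabeledDataset,
         runner: Callable[[LabeledDataset, LabeledDataset, RunConfig],
                          RunResult] = run_pipeline) -> pd.DataFrame:
    """Size sweep of the DSE1 winner, with eta/d_theta rescaled per size."""
    N_ref = best_cfg.network.N_e
    rows = []
    for N_e in sizes:
        cfg = scale_for_size(best_cfg, N_e, N_ref)
        result = runner(train, test, cfg)
        rows.append({"pipeline": cfg.pipeline, "N_e": N_e,
                     "eta": cfg.trace.eta, "d_theta": cfg.network.d_theta,
                     "accuracy": result.accuracy,
                     "config_hash": cfg.config_hash(), "seed": cfg.seed})
    return pd.DataFrame(rows)


def ensemble_majority(member_predictions: np.ndarray,
                      member_scores: np.ndarray | None = None,
                      require_six: bool = True) -> np.ndarray:
    """Majority vote over ensemble members (3 windows x 2 polarities = 6).

    ``member_predictions`` is (n_members, n_patterns).  Vote ties are broken
    by the summed per-class member scores (when given), then by the lower
    class index.
    """
    preds = np.asarray(member_predictions)
    if preds.ndim != 2:
        raise ValueError("member_predictions must be (n_members, n_patterns)")
    n_members, n_patterns = preds.shape
    if require_six and n_members != 6:
        raise ValueError(
            f"expected 6 ensemble members (3 saccades x 2 polarities), got "
            f"{n_members}; pass require_six=False to override")
    K = int(preds.max()) + 1
    out = np.zeros(n_patterns, dtype=np.int64)
    for i in range(n_patterns):
        votes = np.bincount(preds[:, i], minlength=K)
        top = votes.max()
        tied = np.nonzero(votes == top)[0]
        if len(tied) == 1 or member_scores is None:
            out[i] = tied[0]
        else:
            sums = member_scores[:, i, :].sum(axis=0)
            tied_scores = sums[tied]
            out[i] = tied[int(np.argmax(tied_scores))]
    return out


def evaluate_and_report(results: list[RunResult], out_dir) -> dict:
    """Persist a machine-readable table + human-readable summary.

    Returns the report dict; writes ``results.json`` and ``summary.txt`` in
    ``out_dir``.
    """
    import pathlib

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {"runs": [r.to_dict() for r in results]}
    for run in report["runs"]:
        conf = np.asarray(run["confusion"])
        recomputed = float(np.trace(conf) / conf.sum()) if conf.sum() else 0.0
        run["accuracy_recomputed"] = recomputed
    (out_dir / "results.json").write_text(json.dumps(report, indent=2))
    lines = ["pipeline          accuracy  escalations  fallbacks  hash",
             "-" * 60]
    for r in results:
        lines.append(f"{r.pipeline:<18}{r.accuracy:>7.3f}  "
                     f"{r.escalation_passes:>10d}  {r.fallback_count:>9d}  "
                     f"{r.config_hash}")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return report


def default_rate_run_config(seed: int = 0, N_e: int = 100,
                            **kw) -> RunConfig:
    """Desk-scale rate-regime configuration (105 ms presentations)."""
    return RunConfig(
        pipeline="rdstdp",
        network=rate_mode_config(N_e=N_e),
        trace=TraceParams(eta=0.05, tau_xpre=215.0),
        seed=seed, **kw)


def default_temporal_run_config(seed: int = 0, N_e: int = 100,
                                presentation_T: float = 100.0,
                                epochs: int = 2,
                                **kw) -> RunConfig:
    """Desk-scale temporal-regime configuration with SOM enabled."""
    side = math.isqrt(N_e)
    if side * side != N_e:
        raise ValueError("N_e must be square for the SOM grid")
    return RunConfig(
        pipeline="stdp_tempotron",
        network=temporal_mode_config(
            presentation_T=presentation_T, N_e=N_e, d_theta=0.05,
            som=SomConfig(sigma0=side / 4.0)),
        # the short trace reaches ~a tenth of the rate-regime magnitude, so
        # the depression target rescales accordingly
        trace=TraceParams(eta=0.05, tau_xpre=presentation_T / 10.0,
                          x_tar=1.5),
        seed=seed, epochs=epochs, **kw)
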