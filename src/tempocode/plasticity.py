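"""Weight-update rules: trace STDP, fixed-postsynaptic-time STDP, and the
PSTH-derived population-rate rule.

All three share the soft-bounded multiplicative form: the update is scaled by
``(w_max - w)^mu`` and the caller clips into ``[0, w_max]``.

* **Trace STDP** — at each postsynaptic spike,
  ``dw = eta * (x_pre - x_tar) * (w_max - w)^mu`` where ``x_pre`` is the
  presynaptic trace: incremented by ``dx_pre`` per presynaptic spike, decaying
  exponentially with ``tau_xpre``.  With ``tau_xpre`` much larger than the
  presentation the trace approximates a spike *count* (rate regime); with
  ``tau_xpre`` a tenth of the presentation only recent spikes matter (timing
  regime).

* **Fixed-time STDP** — identical formula, but the trace is evaluated at a
  single fixed time ``t*`` (the mean postsynaptic spike time of a reference
  run) instead of the actual postsynaptic spike time.  The winner is still
  chosen by the real first-spike competition; only the learning pretends the
  spike happened at ``t*``.

* **PSTH rule** — a hand-engineered kernel ``h(t) = a*H(t) + b`` derived from
  the peristimulus time histogram ``H`` of the training data (per-ms event
  counts over all patterns and pixels, divided by the number of patterns).
  The presynaptic "trace" of a synapse is ``sum_i h(t_i)`` over its spike
  times (or ``-x_tar`` if it never spiked) and the update is
  ``dw = eta * x_pre * (w_max - w)^mu`` applied at the end of the
  presentation.  ``a`` and ``b`` are fitted so that the depressing (LTD) area
  of ``h`` exceeds the potentiating (LTP) area — required for stability — and
  so that update magnitudes match the trace rule on a calibration batch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .events import EventStream, LabeledDataset

__all__ = [
    "TraceParams",
    "PsthCurve",
    "FixedTimeSpec",
    "CalibrationError",
    "update_trace",
    "trace_at",
    "stdp_update",
    "compute_mean_postspike_time",
    "fixed_time_update",
    "compute_psth",
    "fit_scale_bias",
    "psth_trace",
    "psth_trace_per_pixel",
    "psth_update",
    "BEST_LINEAR_PRESET",
]


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class TraceParams:
    """Trace-STDP parameters.

    tau_xpre may be ``math.inf`` to disable decay entirely (pure spike-count
    regime, useful for the rate-limit analyses).
    """

    eta: float = 0.05
    x_tar: float = 8.0
    dx_pre: float = 1.0
    tau_xpre: float = 215.0
    w_max: float = 1.0
    mu: float = 0.9

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.tau_xpre <= 0 or self.w_max <= 0:
            raise ValueError("eta, tau_xpre and w_max must be positive")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


# Refined presentation-scale operating point found on a linear-scale search
# around the best log-grid cell (105 ms presentations).
BEST_LINEAR_PRESET = {"d_theta": 0.2, "eta": 0.05, "tau_xpre": 215.0}


@dataclass
class PsthCurve:
    """The fitted population-rate learning kernel.

    ``H`` is the per-ms-bin average event count per pattern (over all
    pixels); ``h = a * H + b`` is the learning kernel.  Invariant: the LTD
    area ``sum max(-h, 0) * dt`` strictly exceeds the LTP area
    ``sum max(h, 0) * dt``.
    """

    dt_bin: float
    H: np.ndarray
    a: float
    b: float
    N_patterns: int
    h: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if self.h is None:
            self.h = self.a * self.H + self.b
        else:
            self.h = np.asarray(self.h, dtype=float)
            if not np.allclose(self.h, self.a * self.H + self.b):
                raise ValueError("h must equal a*H + b")
        if self.ltd_area() <= self.ltp_area():
            raise ValueError("stability requires LTD area > LTP area")

    def ltp_area(self) -> float:
        return float(np.maximum(self.h, 0.0).sum() * self.dt_bin)

    def ltd_area(self) -> float:
        return float(np.maximum(-self.h, 0.0).sum() * self.dt_bin)


@dataclass(frozen=True)
class FixedTimeSpec:
    """The fixed postsynaptic evaluation time t* in ms."""

    t_star: float

    def __post_init__(self) -> None:
        if self.t_star < 0:
            raise ValueError("t_star must be >= 0")


def update_trace(x_pre: float | np.ndarray, elapsed: float, n_spikes: int,
                 p: TraceParams) -> float | np.ndarray:
    """Decay a trace by ``elapsed`` ms, then add ``n_spikes`` increments."""
    if elapsed < 0:
        raise ValueError("elapsed must be >= 0")
    decay = 1.0 if math.isinf(p.tau_xpre) else math.exp(-elapsed / p.tau_xpre)
    return x_pre * decay + n_spikes * p.dx_pre


def trace_at(spike_times: np.ndarray, t_eval: float, p: TraceParams) -> float:
    """Event-driven trace value at ``t_eval`` given presyn spikes (ms).

    Spikes at exactly ``t_eval`` are included (their increment has not yet
    decayed); later spikes are ignored.
    """
    x = 0.0
    prev = 0.0
    for ts in np.sort(np.asarray(spike_times, dtype=float)):
        if ts > t_eval:
            break
        x = update_trace(x, ts - prev, 1, p)
        prev = ts
    return float(update_trace(x, t_eval - prev, 0, p))


def stdp_update(w: float | np.ndarray, x_pre: float | np.ndarray,
                p: TraceParams) -> float | np.ndarray:
    """Trace-STDP weight change at a postsynaptic spike (not yet clipped)."""
    return p.eta * (x_pre - p.x_tar) * np.power(p.w_max - w, p.mu)


def apply_update(w: np.ndarray, dw: np.ndarray, w_max: float) -> np.ndarray:
    """Clip ``w + dw`` into [0, w_max] in place."""
    np.clip(w + dw, 0.0, w_max, out=w)
    return w


def compute_mean_postspike_time(records) -> float:
    """Mean over patterns of the first postsynaptic spike time (ms)."""
    times = []
    for r in records:
        if not len(r):
            raise ValueError("a presentation produced no output spike; "
                             "the escalation protocol should prevent this")
        times.append(r.first_spike()[1])
    if not times:
        raise ValueError("no spike records given")
    return float(np.mean(times))


def fixed_time_update(w: float | np.ndarray, x_pre_at_tstar: float | np.ndarray,
                      p: TraceParams) -> float | np.ndarray:
    """Identical to :func:`stdp_update` with the trace frozen at t*."""
    return stdp_update(w, x_pre_at_tstar, p)


def compute_psth(ds: LabeledDataset, dt_bin: float = 1.0,
                 T_ms: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Peristimulus time histogram of a training collection.

    Returns ``(H_prime, H)``: raw per-bin event counts over all patterns and
    pixels, and the per-pattern average ``H = H' / N_patterns``.  Streams must
    be ms-binned (timestamps in ms ticks) and windowed to [0, T).
    """
    if not len(ds):
        raise ValueError("empty collection")
    if T_ms is None:
        T_ms = max(s.duration for s in ds.streams)
    n_bins = int(math.ceil(T_ms / dt_bin))
    H_prime = np.zeros(n_bins)
    for s in ds.streams:
        if len(s):
            bins = np.minimum((s.t / dt_bin).astype(np.int64), n_bins - 1)
            np.add.at(H_prime, bins, 1.0)
    return H_prime, H_prime / len(ds)


def _areas(h: np.ndarray, dt_bin: float) -> tuple[float, float]:
    return (float(np.maximum(h, 0.0).sum() * dt_bin),
            float(np.maximum(-h, 0.0).sum() * dt_bin))


def _solve_bias(H: np.ndarray, a: float, dt_bin: float,
                kappa: float) -> float:
    """Bisect on b so that LTD area = kappa * LTP area for h = a*H + b."""
    def excess(b: float) -> float:
        ltp, ltd = _areas(a * H + b, dt_bin)
        return ltd - kappa * ltp

    lo, hi = -a * float(H.max()) - 1.0, a * float(H.max()) + 1.0
    # excess decreases in b: lower b -> more LTD, less LTP
    if excess(lo) < 0 or excess(hi) > 0:
        raise CalibrationError("no feasible bias for the LTD/LTP margin")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            lo = mid
        else:
            hi = mid
    return lo  # last b with LTD area >= kappa * LTP area


def fit_scale_bias(H: np.ndarray, reference_magnitude: float,
                   calibration_counts: list[np.ndarray] | None = None,
                   dt_bin: float = 1.0, kappa: float = 1.1,
                   p: TraceParams | None = None,
                   tol: float = 0.10) -> PsthCurve:
    """Fit ``h = a*H + b`` under the stability and magnitude conditions.

    ``reference_magnitude`` is the mean |dw| produced by the trace rule on a
    calibration batch; ``calibration_counts`` holds, per calibration pattern,
    an (n_pixels, n_bins) matrix of presynaptic spike counts used to measure
    this rule's mean |dw| at the same midpoint weight.  For a given scale
    ``a``, the bias is solved by bisection so the LTD area is ``kappa`` x the
    LTP area; an outer bisection on ``a`` matches the magnitude within
    ``tol`` (10% by default).
    """
    H = np.asarray(H, dtype=float)
    p = p or TraceParams()
    if H.max() <= 0:
        raise CalibrationError("degenerate PSTH: no events")
    if reference_magnitude <= 0:
        raise CalibrationError("reference magnitude must be positive")
    if np.ptp(H) == 0:
        # flat histogram: any purely depressing constant kernel satisfies
        # the area inequality (LTP area is 0); match the magnitude directly
        warnings.warn("constant PSTH: kernel has no potentiating part",
                      RuntimeWarning)
        def mag_of(m: float) -> float:
            curve = PsthCurve(dt_bin=dt_bin, H=H, a=m / (2 * H[0]),
                              b=-1.5 * m, N_patterns=0)
            if calibration_counts is None:
                return float(np.abs(curve.h).mean())
            w0 = 0.5 * p.w_max
            scale = (p.w_max - w0) ** p.mu
            mags = []
            for counts in calibration_counts:
                x = counts @ curve.h
                x[counts.sum(axis=1) == 0] = -p.x_tar
                mags.append(np.abs(p.eta * x * scale).mean())
            return float(np.mean(mags))
        lo, hi = 1e-12, 1e-12
        for _ in range(80):
            hi *= 2.0
            if mag_of(hi) >= reference_magnitude:
                break
        else:
            raise CalibrationError("could not match the magnitude")
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if mag_of(mid) < reference_magnitude:
                lo = mid
            else:
                hi = mid
        m = 0.5 * (lo + hi)
        return PsthCurve(dt_bin=dt_bin, H=H, a=m / (2 * H[0]), b=-1.5 * m,
                         N_patterns=0)

    def mean_mag(a: float) -> tuple[float, float]:
        b = _solve_bias(H, a, dt_bin, kappa)
        h = a * H + b
        if calibration_counts is None:
            # proxy: magnitude of the kernel itself
            mag = float(np.abs(h).mean())
        else:
            w0 = 0.5 * p.w_max
            scale = (p.w_max - w0) ** p.mu
            mags = []
            for counts in calibration_counts:
                x = counts @ h                       # per-pixel h sums
                x[counts.sum(axis=1) == 0] = -p.x_tar
                mags.append(np.abs(p.eta * x * scale).mean())
            mag = float(np.mean(mags))
        return mag, b

    if reference_magnitude <= 0:
        raise CalibrationError("reference magnitude must be positive")
    # magnitude grows monotonically with a; bracket then bisect
    a_lo, a_hi = 1e-8, 1e-8
    for _ in range(80):
        a_hi *= 2.0
        if mean_mag(a_hi)[0] >= reference_magnitude:
            break
    else:
        raise CalibrationError("could not bracket the magnitude condition")
    for _ in range(100):
        a_mid = 0.5 * (a_lo + a_hi)
        if mean_mag(a_mid)[0] < reference_magnitude:
            a_lo = a_mid
        else:
            a_hi = a_mid
    a = 0.5 * (a_lo + a_hi)
    mag, b = mean_mag(a)
    if abs(mag - reference_magnitude) > tol * reference_magnitude:
        raise CalibrationError(
            f"magnitude match failed: got {mag:.3g}, "
            f"wanted {reference_magnitude:.3g} within {tol:.0%}")
    return PsthCurve(dt_bin=dt_bin, H=H, a=a, b=b, N_patterns=0)


def psth_trace(spike_times: np.ndarray, curve: PsthCurve,
               x_tar: float) -> float:
    """Population-rate 'trace' of one synapse: sum of h at its spike times.

    A synapse whose presynaptic neuron never spiked is depressed by
    ``-x_tar`` — mirroring the trace rule, where a silent input sits at
    ``x_pre = 0`` and the update is ``-eta * x_tar * (...)``.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if len(spike_times) == 0:
        return -x_tar
    bins = np.minimum((spike_times / curve.dt_bin).astype(np.int64),
                      len(curve.h) - 1)
    return float(curve.h[bins].sum())


def psth_trace_per_pixel(stream: EventStream, curve: PsthCurve,
                         x_tar: float, n_inputs: int) -> np.ndarray:
    """Vectorised :func:`psth_trace` over every input pixel of a stream."""
    x = np.full(n_inputs, -x_tar)
    if len(stream):
        pix = stream.pixel_index()
        bins = np.minimum((stream.t / curve.dt_bin).astype(np.int64),
                          len(curve.h) - 1)
        sums = np.zeros(n_inputs)
        np.add.at(sums, pix, curve.h[bins])
        spiked = np.zeros(n_inputs, dtype=bool)
        spiked[pix] = True
        x[spiked] = sums[spiked]
    return x


def psth_update(w: float | np.ndarray, x_pre: float | np.ndarray,
                p: TraceParams) -> float | np.ndarray:
    """Population-rate weight change: ``eta * x_pre * (w_max - w)^mu``."""
    return p.eta * x_pre * np.power(p.w_max - w, p.mu)
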