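"""Readout layers over the excitatory population's output spikes.

Two readouts, matching the two coding regimes:

* **Unsupervised labeling + rate classification** — after unsupervised
  training, each excitatory neuron is assigned to the class it responds to
  most strongly on the training set (labels are used *only* here, never
  during training).  A test pattern is then classified by the mean spike
  count of each class's neurons — a pure rate readout, blind to spike order.

* **Tempotron** — a supervised spiking classifier over the output spike
  *sequences*.  Each class unit sums dual-exponential kernels of its
  afferents' spikes; a pattern belongs to a unit if the peak potential
  crosses threshold, and on errors the afferent weights are nudged by the
  kernel contributions evaluated at the time of the maximal potential.
  Multiclass decisions take the argmax of peak potentials (one-vs-rest).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import SpikeRecord

__all__ = [
    "NeuronLabels",
    "assign_labels",
    "classify_rate",
    "TempotronModel",
    "tempotron_kernel",
    "tempotron_potential",
    "train_tempotron",
    "classify_sequence",
]

UNASSIGNED = -1


@dataclass
class NeuronLabels:
    """Per-neuron class assignment from summed training-set responses."""

    response: np.ndarray      # (N_e, K) summed spike counts per class
    label: np.ndarray         # (N_e,) class id, or UNASSIGNED for silent rows
    fallback_class: int       # most frequent training class

    @property
    def n_assigned(self) -> int:
        return int((self.label != UNASSIGNED).sum())


def assign_labels(records: list[SpikeRecord], labels: np.ndarray,
                  N_e: int) -> NeuronLabels:
    """Assign each neuron the class it most strongly responds to.

    ``records`` are the training-set presentations of the *trained* network
    (plasticity off).  Ties break toward the lower class index; silent
    neurons stay unassigned and never vote.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if len(records) != len(labels):
        raise ValueError("records and labels length mismatch")
    K = int(labels.max()) + 1
    response = np.zeros((N_e, K))
    for rec, y in zip(records, labels):
        response[:, y] += rec.counts(N_e)
    assigned = response.sum(axis=1) > 0
    label = np.where(assigned, response.argmax(axis=1), UNASSIGNED)
    if not assigned.any():
        raise ValueError("degenerate training: every neuron is silent")
    counts = np.bincount(labels, minlength=K)
    return NeuronLabels(response, label.astype(np.int64),
                        fallback_class=int(counts.argmax()))


def classify_rate(neuron_labels: NeuronLabels,
                  record: SpikeRecord) -> tuple[int, bool]:
    """Rate readout: argmax over classes of mean spikes per labeled neuron.

    Returns ``(predicted class, fallback_used)``; the fallback (most frequent
    training class) fires when no labeled neuron spiked.  The score is a mean
    per labeled neuron, so classes with many neurons are not favoured.
    """
    K = neuron_labels.response.shape[1]
    counts = record.counts(len(neuron_labels.label))
    scores = np.zeros(K)
    for k in range(K):
        members = neuron_labels.label == k
        if members.any():
            scores[k] = counts[members].mean()
    if scores.max() <= 0:
        return neuron_labels.fallback_class, True
    return int(scores.argmax()), False


@dataclass
class TempotronModel:
    """One-vs-rest tempotron over ``n_afferents`` spike trains.

    The kernel ``V0 * (exp(-t/tau) - exp(-t/tau_s))`` is normalised to unit
    peak.  ``threshold`` is the binary decision level per class unit;
    multiclass predictions use the peak-potential argmax.
    """

    n_afferents: int
    n_classes: int
    tau: float
    tau_s: float = None  # type: ignore[assignment]
    threshold: float = 1.0
    lam: float = 0.1
    max_epochs: int = 50
    w_init: float = 0.01
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tau_s is None:
            self.tau_s = self.tau / 4.0
        if not self.tau_s < self.tau:
            raise ValueError("require tau_s < tau")
        if self.weights is None:
            # small uniform start: gives the flat potential a meaningful
            # peak time (that of maximal total input) so learning can begin
            self.weights = np.full((self.n_classes, self.n_afferents),
                                   self.w_init)

    @property
    def V0(self) -> float:
        t_pk = (self.tau * self.tau_s / (self.tau - self.tau_s)
                * math.log(self.tau / self.tau_s))
        return 1.0 / (math.exp(-t_pk / self.tau)
                      - math.exp(-t_pk / self.tau_s))


def tempotron_kernel(model: TempotronModel, dt_s: np.ndarray) -> np.ndarray:
    """Unit-peak dual-exponential kernel at lags ``dt_s >= 0`` (0 otherwise)."""
    dt_s = np.asarray(dt_s, dtype=float)
    k = model.V0 * (np.exp(-dt_s / model.tau) - np.exp(-dt_s / model.tau_s))
    return np.where(dt_s >= 0, k, 0.0)


def _contribution_matrix(model: TempotronModel, record: SpikeRecord,
                         t_grid: np.ndarray) -> np.ndarray:
    """Per-afferent kernel sums on a time grid: (n_afferents, len(t_grid))."""
    contrib = np.zeros((model.n_afferents, len(t_grid)))
    for j, ts in zip(record.neuron_ids, record.times):
        contrib[j] += tempotron_kernel(model, t_grid - ts)
    return contrib


def _time_grid(model: TempotronModel, record: SpikeRecord,
               resolution: float = 1.0) -> np.ndarray:
    return np.arange(0.0, record.presentation_T + 1e-9, resolution)


def tempotron_potential(model: TempotronModel, class_id: int,
                        record: SpikeRecord, t: float) -> float:
    """Membrane value of one class unit at time t."""
    v = 0.0
    for j, ts in zip(record.neuron_ids, record.times):
        if ts <= t:
            v += model.weights[class_id, j] * float(
                tempotron_kernel(model, np.array([t - ts]))[0])
    return v


def _peaks(model: TempotronModel, record: SpikeRecord
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Peak potential and its time per class; also the contribution matrix."""
    t_grid = _time_grid(model, record)
    contrib = _contribution_matrix(model, record, t_grid)
    V = model.weights @ contrib            # (K, n_grid)
    idx = V.argmax(axis=1)
    return V[np.arange(model.n_classes), idx], t_grid[idx], contrib


def train_tempotron(model: TempotronModel, records: list[SpikeRecord],
                    labels: np.ndarray, seed: int = 0) -> TempotronModel:
    """One-vs-rest tempotron training on labeled spike records.

    On each epoch the patterns are visited in a shuffled order (seeded).  A
    class unit is updated only on errors: potentiate every afferent by
    ``lam`` x its kernel contribution at the peak time when the true class
    failed to cross threshold; depress likewise on a false alarm.  Stops
    early once an epoch is error-free; non-convergence is recorded on the
    model (``converged``), not raised.
    """
    labels = np.asarray(labels, dtype=np.int64)
    rng = np.random.default_rng(seed)
    model.converged = False
    for epoch in range(model.max_epochs):
        order = rng.permutation(len(records))
        n_errors = 0
        for i in order:
            record, y = records[i], labels[i]
            peaks, t_pk, contrib = _peaks(model, record)
            t_grid = _time_grid(model, record)
            for c in range(model.n_classes):
                should_fire = c == y
                fired = peaks[c] >= model.threshold
                if fired == should_fire:
                    continue
                n_errors += 1
                col = np.searchsorted(t_grid, t_pk[c])
                dw = model.lam * contrib[:, col]
                model.weights[c] += dw if should_fire else -dw
        if n_errors == 0:
            model.converged = True
            break
    return model


def classify_sequence(model: TempotronModel, record: SpikeRecord) -> int:
    """Argmax of peak potential over the presentation; ties to lower index."""
    if not len(record):
        return 0  # empty record: all peaks are zero, tie-break to class 0
    peaks, _, _ = _peaks(model, record)
    return int(peaks.argmax())
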