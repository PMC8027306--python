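"""Time-collapse of event streams and the collapsed-frame classifier baseline.

Collapsing sums each pixel's in-window events and divides by the pattern's
maximum per-pixel count:

    C[x] = sum_i g(t_i at x) / max_y sum_i g(t_i at y)

with g the window gate (1 inside the window, 0 outside).  Normalisation is
per pattern, so low-rate patterns are rescaled up; a pattern with no in-window
events maps to the all-zero frame.  A classifier trained on these frames sees
only spike *counts* — any accuracy it achieves needs no spike timing, which is
exactly what the baseline measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EventStream, LabeledDataset, Polarity, WindowSpec

__all__ = [
    "CollapsedFrame",
    "FrameSet",
    "FrameClassifierSpec",
    "TABLE_CNN_STACK",
    "collapse",
    "collapse_dataset",
    "train_frame_classifier",
    "evaluate",
    "EvalResult",
]


@dataclass
class CollapsedFrame:
    """Normalized spike-count image of one pattern; values in [0, 1]."""

    values: np.ndarray  # (height, width)
    label: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("collapsed-frame values must lie in [0, 1]")


@dataclass
class FrameSet:
    frames: list[CollapsedFrame]
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = np.array([f.label for f in self.frames],
                                   dtype=np.int64)
        else:
            self.labels = np.asarray(self.labels, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.frames)

    def as_matrix(self) -> np.ndarray:
        return np.stack([f.values.ravel() for f in self.frames])


def collapse(stream: EventStream, w: WindowSpec | None = None) -> CollapsedFrame:
    """Collapse a stream to a normalized per-pixel count image.

    ``w`` defaults to the full recording with both polarities.  The window
    gate keeps events with ``t0 <= t < t1`` (and matching polarity); counts
    are normalized by the maximum per-pixel count of this pattern.
    """
    if w is None:
        mask = np.ones(len(stream), dtype=bool)
    else:
        mask = (stream.t >= w.t0) & (stream.t < w.t1)
        if w.polarity is not Polarity.BOTH:
            mask &= stream.p == w.polarity.value
    counts = np.zeros(stream.height * stream.width, dtype=np.int64)
    np.add.at(counts, stream.pixel_index()[mask], 1)
    peak = counts.max()
    values = counts / peak if peak > 0 else counts.astype(float)
    return CollapsedFrame(values.reshape(stream.height, stream.width),
                          label=stream.label)


def collapse_dataset(ds: LabeledDataset,
                     w: WindowSpec | None = None) -> FrameSet:
    """Collapse every pattern; labels are carried through unchanged."""
    return FrameSet([collapse(s, w) for s in ds.streams], ds.labels.copy())


# The reference convolutional stack used for full-scale frame classification:
# two 3x3x32 ReLU convs, 2x2 max-pool, dropout .25, two 3x3x64 ReLU convs,
# 2x2 max-pool, dropout .25, dense 128, dropout .5, dense softmax.
TABLE_CNN_STACK: tuple[tuple[str, dict], ...] = (
    ("conv2d", {"filters": 32, "kernel": (3, 3), "activation": "relu"}),
    ("conv2d", {"filters": 32, "kernel": (3, 3), "activation": "relu"}),
    ("maxpool2d", {"size": (2, 2)}),
    ("dropout", {"rate": 0.25}),
    ("conv2d", {"filters": 64, "kernel": (3, 3), "activation": "relu"}),
    ("conv2d", {"filters": 64, "kernel": (3, 3), "activation": "relu"}),
    ("maxpool2d", {"size": (2, 2)}),
    ("dropout", {"rate": 0.25}),
    ("dense", {"units": 128}),
    ("dropout", {"rate": 0.5}),
    ("dense", {"units": "n_classes", "activation": "softmax"}),
)


@dataclass
class FrameClassifierSpec:
    """Frame-classifier configuration.

    ``backend="linear"`` is a multinomial logistic regression — the desk-scale
    baseline ("an algorithm that purely works on spatial data").
    ``backend="cnn"`` is the reference convolutional stack (cross-entropy
    loss, Adadelta optimizer); it requires torch and is intended for
    full-scale runs on real sensor data.
    """

    backend: str = "linear"
    layers: tuple = TABLE_CNN_STACK
    loss: str = "cross_entropy"
    optimizer: str = "adadelta"
    epochs: int = 100
    C: float = 1.0  # inverse L2 regularisation of the linear backend

    def __post_init__(self) -> None:
        if self.backend not in ("linear", "cnn"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class FrameClassifier:
    """Trained frame classifier with a ``predict(frames) -> labels`` surface."""

    def __init__(self, model, spec: FrameClassifierSpec):
        self._model = model
        self.spec = spec

    def predict(self, frames: FrameSet | CollapsedFrame) -> np.ndarray:
        if isinstance(frames, CollapsedFrame):
            X = frames.values.ravel()[None]
        else:
            X = frames.as_matrix()
        return self._model.predict(X).astype(np.int64)


def train_frame_classifier(frames: FrameSet,
                           spec: FrameClassifierSpec | None = None,
                           seed: int = 0) -> FrameClassifier:
    """Fit a classifier on collapsed frames (deterministic given the seed)."""
    spec = spec or FrameClassifierSpec()
    labels = frames.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    if spec.backend == "cnn":
        try:
            import torch  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "the cnn backend requires torch; use backend='linear' for "
                "desk-scale runs") from exc
        raise NotImplementedError(
            "cnn backend: build the TABLE_CNN_STACK in your torch "
            "environment; desk-scale analyses use the linear backend")
    from sklearn.linear_model import LogisticRegression

    model = LogisticRegression(
        C=spec.C, max_iter=max(spec.epochs * 10, 200), random_state=seed)
    model.fit(frames.as_matrix(), labels)
    return FrameClassifier(model, spec)


@dataclass
class EvalResult:
    accuracy: float
    confusion: np.ndarray  # (K, K), rows true, cols predicted
    n: int


def evaluate(classifier: FrameClassifier, frames: FrameSet) -> EvalResult:
    """Fraction correct on labeled frames, with the confusion matrix."""
    pred = classifier.predict(frames)
    true = frames.labels
    K = int(max(true.max(), pred.max())) + 1
    confusion = np.zeros((K, K), dtype=np.int64)
    np.add.at(confusion, (true, pred), 1)
    return EvalResult(float(np.trace(confusion) / len(true)), confusion,
                      len(true))
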