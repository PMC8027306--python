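"""Address-event representation (AER) streams: data model, I/O, windowing.

An event camera reports a sparse stream of ``(t, x, y, polarity)`` tuples —
one per pixel-level brightness change — instead of frames.  This module holds
the in-memory representation used by every other stage (column-oriented numpy
arrays), readers for the two on-disk dialects we support (the de-facto 5-byte
N-MNIST binary and a plain CSV), the saccade-window presets of image-derived
datasets, and the windowing / ms-binning primitives.

Times are integer microseconds internally.  Windows are half-open
``[t0, t1)``; coordinates are 0-based with ``x`` the column and ``y`` the row.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import numpy as np

__all__ = [
    "Polarity",
    "Event",
    "EventStream",
    "WindowSpec",
    "LabeledDataset",
    "read_nmnist_bin",
    "read_event_csv",
    "write_event_csv",
    "filter_window",
    "bin_to_ms",
    "per_pixel_trains",
    "save_dataset",
    "load_dataset",
    "SACCADE1_ON",
    "SACCADE2_ON",
    "SACCADE3_ON",
    "FULL_SPAN_BOTH",
]

US_PER_MS = 1000

class FormatError(ValueError):
    """Raised when an on-disk event file violates its dialect."""


class Polarity(Enum):
    OFF = 0
    ON = 1
    BOTH = 2


@dataclass(frozen=True)
class Event:
    """A single address-event: time in microseconds, pixel address, polarity."""

    t: int
    x: int
    y: int
    p: int

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"negative timestamp {self.t}")
        if self.p not in (0, 1):
            raise ValueError(f"polarity must be 0 or 1, got {self.p}")


@dataclass
class EventStream:
    """Time-ordered events on a fixed sensor grid.

    Columns ``t`` (microseconds, sorted ascending), ``x``, ``y``, ``p`` are
    parallel integer arrays.  ``duration`` is the recording span in
    microseconds; every event satisfies ``t < duration`` and lies inside the
    ``width`` x ``height`` grid.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    p: np.ndarray
    width: int
    height: int
    duration: int
    label: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.p = np.asarray(self.p, dtype=np.int64)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.p) == n):
            raise ValueError("event columns must have equal length")
        self.validate()

    def validate(self) -> None:
        if len(self.t) and np.any(np.diff(self.t) < 0):
            raise ValueError("events must be sorted by t ascending")
        if len(self.t):
            if self.t[0] < 0 or self.t[-1] >= self.duration:
                raise ValueError("event timestamps must lie in [0, duration)")
            if (self.x.min() < 0 or self.x.max() >= self.width
                    or self.y.min() < 0 or self.y.max() >= self.height):
                raise ValueError("event coordinates out of sensor bounds")
            if not np.isin(self.p, (0, 1)).all():
                raise ValueError("polarity values must be 0 or 1")

    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self) -> Iterator[Event]:
        for i in range(len(self.t)):
            yield Event(int(self.t[i]), int(self.x[i]), int(self.y[i]), int(self.p[i]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        return (
            self.width == other.width
            and self.height == other.height
            and self.duration == other.duration
            and self.label == other.label
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.p, other.p)
        )

    @classmethod
    def from_arrays(
        cls,
        t: np.ndarray,
        x: np.ndarray,
        y: np.ndarray,
        p: np.ndarray,
        width: int,
        height: int,
        duration: int | None = None,
        label: int | None = None,
        sort: bool = True,
    ) -> "EventStream":
        t = np.asarray(t, dtype=np.int64)
        x = np.asarray(x, dtype=np.int64)
        y = np.asarray(y, dtype=np.int64)
        p = np.asarray(p, dtype=np.int64)
        if sort and len(t):
            order = np.argsort(t, kind="stable")
            t, x, y, p = t[order], x[order], y[order], p[order]
        if duration is None:
            duration = int(t[-1]) + 1 if len(t) else 0
        return cls(t, x, y, p, width, height, duration, label)

    @classmethod
    def empty(cls, width: int, height: int, duration: int = 0,
              label: int | None = None) -> "EventStream":
        z = np.empty(0, dtype=np.int64)
        return cls(z, z.copy(), z.copy(), z.copy(), width, height, duration, label)

    def pixel_index(self) -> np.ndarray:
        """Flat pixel index ``y * width + x`` per event."""
        return self.y * self.width + self.x


@dataclass(frozen=True)
class WindowSpec:
    """Half-open time window ``[t0, t1)`` in microseconds with a polarity gate."""

    t0: int
    t1: int
    polarity: Polarity = Polarity.BOTH

    def __post_init__(self) -> None:
        if not self.t0 < self.t1:
            raise ValueError(f"require t0 < t1, got [{self.t0}, {self.t1})")


# Saccade presets of image-derived AER datasets: three 105 ms camera sweeps,
# plus a 45 ms tail included only in the full-span preset.
SACCADE_MS = 105
SACCADE1_ON = WindowSpec(0, 105 * US_PER_MS, Polarity.ON)
SACCADE2_ON = WindowSpec(105 * US_PER_MS, 210 * US_PER_MS, Polarity.ON)
SACCADE3_ON = WindowSpec(210 * US_PER_MS, 315 * US_PER_MS, Polarity.ON)
FULL_SPAN_BOTH = WindowSpec(0, 360 * US_PER_MS, Polarity.BOTH)


def saccade_window(index: int, polarity: Polarity = Polarity.ON) -> WindowSpec:
    """Window for saccade 1, 2 or 3 (each 105 ms) with the given polarity."""
    if index not in (1, 2, 3):
        raise ValueError("saccade index must be 1, 2 or 3")
    t0 = (index - 1) * SACCADE_MS * US_PER_MS
    return WindowSpec(t0, t0 + SACCADE_MS * US_PER_MS, polarity)


def read_nmnist_bin(path, width: int = 34, height: int = 34) -> EventStream:
    """Decode a 5-byte-per-event N-MNIST-dialect binary file.

    Record layout (40 bits, big-endian): byte 0 = x, byte 1 = y, byte 2 bit 7 =
    polarity, remaining 23 bits = timestamp in microseconds.
    """
    raw = np.fromfile(path, dtype=np.uint8)
    if raw.size % 5 != 0:
        raise FormatError(
            f"{path}: file length {raw.size} is not a multiple of 5 bytes")
    rec = raw.reshape(-1, 5).astype(np.int64)
    x = rec[:, 0]
    y = rec[:, 1]
    p = rec[:, 2] >> 7
    t = ((rec[:, 2] & 0x7F) << 16) | (rec[:, 3] << 8) | rec[:, 4]
    bad = np.nonzero((x >= width) | (y >= height))[0]
    if bad.size:
        raise FormatError(
            f"{path}: record {int(bad[0])} has coordinates "
            f"({int(x[bad[0]])}, {int(y[bad[0]])}) outside {width}x{height}")
    return EventStream.from_arrays(t, x, y, p, width, height)


CSV_HEADER = ["t_us", "x", "y", "p"]


def write_event_csv(stream: EventStream, path) -> None:
    """Write a stream in the plain ``t_us,x,y,p`` CSV dialect.

    Sensor dimensions and duration travel in a ``# width=.. height=..
    duration=..`` comment line so the round trip is exact.
    """
    with open(path, "w", newline="") as fh:
        fh.write(f"# width={stream.width} height={stream.height} "
                 f"duration={stream.duration}\n")
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for i in range(len(stream)):
            writer.writerow([int(stream.t[i]), int(stream.x[i]),
                             int(stream.y[i]), int(stream.p[i])])


def read_event_csv(path, width: int | None = None,
                   height: int | None = None) -> EventStream:
    """Read the ``t_us,x,y,p`` CSV dialect written by :func:`write_event_csv`.

    ``width``/``height`` may be given explicitly for headerless exports from
    other tools; a metadata comment line, when present, takes precedence.
    """
    duration = None
    rows: list[list[int]] = []
    with open(path, newline="") as fh:
        lineno = 0
        header_seen = False
        for line in fh:
            lineno += 1
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        key, _, val = token.partition("=")
                        if key == "width":
                            width = int(val)
                        elif key == "height":
                            height = int(val)
                        elif key == "duration":
                            duration = int(val)
                continue
            fields = [f.strip() for f in line.split(",")]
            if not header_seen:
                if fields != CSV_HEADER:
                    raise FormatError(
                        f"{path}:{lineno}: expected header "
                        f"'{','.join(CSV_HEADER)}', got '{line}'")
                header_seen = True
                continue
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields")
            try:
                t, x, y, p = (int(f) for f in fields)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field") from exc
            if p not in (0, 1):
                raise FormatError(
                    f"{path}:{lineno}: polarity {p} not in {{0, 1}}")
            rows.append([t, x, y, p])
        if not header_seen:
            raise FormatError(f"{path}: missing '{','.join(CSV_HEADER)}' header")
    if width is None or height is None:
        raise FormatError(f"{path}: sensor dimensions unknown "
                          "(no metadata line and none supplied)")
    arr = np.array(rows, dtype=np.int64).reshape(-1, 4)
    return EventStream.from_arrays(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3],
                                   width, height, duration=duration)


def filter_window(stream: EventStream, w: WindowSpec) -> EventStream:
    """Keep events with ``t0 <= t < t1`` and matching polarity.

    Timestamps are re-zeroed to ``t - t0`` and the result's duration is the
    window length, so a windowed saccade looks like a standalone recording.
    """
    mask = (stream.t >= w.t0) & (stream.t < w.t1)
    if w.polarity is not Polarity.BOTH:
        mask &= stream.p == w.polarity.value
    return EventStream(
        stream.t[mask] - w.t0, stream.x[mask], stream.y[mask], stream.p[mask],
        stream.width, stream.height, duration=w.t1 - w.t0, label=stream.label)


def bin_to_ms(stream: EventStream) -> EventStream:
    """Reduce time resolution: each timestamp becomes ``floor(t / 1000)`` ms.

    Returned timestamps are in millisecond ticks (not microseconds); duplicate
    (pixel, ms) events are retained and ordering is preserved.
    """
    return EventStream(
        stream.t // US_PER_MS, stream.x.copy(), stream.y.copy(), stream.p.copy(),
        stream.width, stream.height,
        duration=-(-stream.duration // US_PER_MS), label=stream.label)


def per_pixel_trains(stream: EventStream) -> dict[tuple[int, int], np.ndarray]:
    """Split a stream into per-pixel spike-time lists.

    Returns a mapping ``(x, y) -> sorted array of spike times``; pixels with no
    events are absent.  The union of all lists is the event multiset.
    """
    trains: dict[tuple[int, int], np.ndarray] = {}
    if not len(stream):
        return trains
    idx = stream.pixel_index()
    order = np.argsort(idx, kind="stable")
    idx_sorted = idx[order]
    t_sorted = stream.t[order]
    boundaries = np.nonzero(np.diff(idx_sorted))[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(idx_sorted)]))
    for s, e in zip(starts, ends):
        flat = int(idx_sorted[s])
        key = (flat % stream.width, flat // stream.width)
        trains[key] = t_sorted[s:e].copy()
    return trains


@dataclass
class LabeledDataset:
    """A labeled collection of event streams on a common sensor grid."""

    streams: list[EventStream]
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    width: int = 0
    height: int = 0

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = np.array(
                [s.label for s in self.streams], dtype=np.int64)
        else:
            self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.streams):
            raise ValueError("labels and streams length mismatch")
        if self.streams:
            if not self.width:
                self.width = self.streams[0].width
            if not self.height:
                self.height = self.streams[0].height
            for s in self.streams:
                if (s.width, s.height) != (self.width, self.height):
                    raise ValueError("heterogeneous sensor dimensions")

    def __len__(self) -> int:
        return len(self.streams)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def map_streams(self, fn) -> "LabeledDataset":
        return LabeledDataset([fn(s) for s in self.streams],
                              self.labels.copy())


def save_dataset(ds: LabeledDataset, path) -> None:
    """Archive a labeled dataset as an NPZ of per-pattern event arrays."""
    arrays: dict[str, np.ndarray] = {
        "labels": ds.labels,
        "dims": np.array([ds.width, ds.height], dtype=np.int64),
        "durations": np.array([s.duration for s in ds.streams], dtype=np.int64),
    }
    for i, s in enumerate(ds.streams):
        arrays[f"events_{i:06d}"] = np.stack([s.t, s.x, s.y, s.p]) if len(s) \
            else np.empty((4, 0), dtype=np.int64)
    np.savez_compressed(path, **arrays)


def load_dataset(path) -> LabeledDataset:
    with np.load(path) as npz:
        labels = npz["labels"]
        width, height = (int(v) for v in npz["dims"])
        durations = npz["durations"]
        streams = []
        for i, label in enumerate(labels):
            e = npz[f"events_{i:06d}"]
            streams.append(EventStream(
                e[0], e[1], e[2], e[3], width, height,
                duration=int(durations[i]), label=int(label)))
    return LabeledDataset(streams, labels)
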