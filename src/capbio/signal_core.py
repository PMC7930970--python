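"""Core signal containers, the ADC digitization model, and plain-text I/O.

Everything downstream (synthesis, ECG/EMG analysis, HRV) works on
:class:`TimeSeries`: a uniformly sampled voltage trace with an explicit
sampling rate and start time.  All times are seconds from record start,
sample indices are 0-based, and intervals are half-open ``[start, end)``.

The canonical on-disk representation is delimited text: a signal table has
one ``time_s`` column plus one column per channel; an annotation table has
``time_s`` and ``label`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignalError",
    "SignalIOError",
    "TimeSeries",
    "QuantizerSpec",
    "EventAnnotations",
    "quantize",
    "slice_series",
    "read_signal_table",
    "write_signal_table",
    "read_annotations",
    "write_annotations",
]


class SignalError(ValueError):
    """Invalid signal, configuration, or operation argument."""


class SignalIOError(SignalError):
    """Malformed signal or annotation file."""


@dataclass
class TimeSeries:
    """Uniformly sampled real-valued voltage signal.

    Parameters
    ----------
    samples : array-like of float
        Sample values in volts.
    fs : float
        Sampling rate in Hz; must be positive.
    t0 : float
        Time of the first sample, seconds from record start.
    label : str
        Channel name (e.g. ``"ECG_ref"``, ``"cECG"``).

    The time of sample ``i`` is exactly ``t0 + i / fs``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise SignalError("samples must be one-dimensional")
        if not self.fs > 0:
            raise SignalError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, ``t0 + arange(n)/fs``."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        """Record span in seconds (n samples cover ``n/fs`` seconds)."""
        return self.samples.size / self.fs

    @property
    def end(self) -> float:
        """Time just past the last sample (half-open record end)."""
        return self.t0 + self.duration

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "TimeSeries":
        """Copy of this series with new sample values (same clock)."""
        return TimeSeries(samples, self.fs, self.t0,
                          self.label if label is None else label)


@dataclass(frozen=True)
class QuantizerSpec:
    """Uniform mid-rise ADC model: ``2**bits`` levels spanning [vmin, vmax].

    Defaults mirror a 16-bit converter with a ±10 V input range.
    """

    bits: int = 16
    vmin: float = -10.0
    vmax: float = 10.0

    def __post_init__(self) -> None:
        if self.bits < 2:
            raise SignalError(f"quantizer needs >= 2 bits, got {self.bits}")
        if not self.vmax > self.vmin:
            raise SignalError("quantizer range must satisfy vmax > vmin")

    @property
    def lsb(self) -> float:
        """Width of one quantization step in volts."""
        return (self.vmax - self.vmin) / 2**self.bits


@dataclass
class EventAnnotations:
    """Ordered event time stamps, e.g. the recorded two-cough cycle marks."""

    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_label: dict[str, float] = {}
        for t, label in self.events:
            prev = by_label.get(label)
            if prev is not None and t <= prev:
                raise SignalError(
                    f"annotation times for label {label!r} must be strictly "
                    f"increasing ({t} follows {prev})")
            by_label[label] = t

    def __len__(self) -> int:
        return len(self.events)

    def times(self, label: str | None = None) -> np.ndarray:
        """Event times, optionally restricted to one label."""
        return np.array([t for t, lab in self.events
                         if label is None or lab == label])


def quantize(ts: TimeSeries, q: QuantizerSpec = QuantizerSpec()) -> TimeSeries:
    """Map samples onto the quantizer's discrete levels.

    Mid-rise convention: level ``k`` sits at ``vmin + (k + 0.5) * lsb`` for
    ``k = 0 .. 2**bits - 1``, so any in-range sample lands within half an
    LSB of its level.  Out-of-range samples are clipped to the extreme
    levels.
    """
    delta = q.lsb
    clipped = np.clip(ts.samples, q.vmin, q.vmax)
    idx = np.floor((clipped - q.vmin) / delta)
    idx = np.minimum(idx, 2**q.bits - 1)
    return ts.with_samples(q.vmin + (idx + 0.5) * delta)


def slice_series(ts: TimeSeries, start: float, end: float) -> TimeSeries:
    """Extract the half-open time interval ``[start, end)``.

    Non-sample-aligned boundaries round start up and end down to sample
    times, so two adjacent slices partition their union exactly.
    """
    if not (ts.t0 <= start < end <= ts.end + 0.5 / ts.fs):
        raise SignalError(
            f"slice [{start}, {end}) outside record [{ts.t0}, {ts.end})")
    # tiny guard so float-exact boundaries are not pushed to the next sample
    i0 = int(np.ceil((start - ts.t0) * ts.fs - 1e-9))
    i1 = int(np.ceil((end - ts.t0) * ts.fs - 1e-9))
    i1 = min(i1, ts.samples.size)
    if i1 <= i0:
        raise SignalError(f"slice [{start}, {end}) contains no samples")
    return TimeSeries(ts.samples[i0:i1], ts.fs, ts.t0 + i0 / ts.fs, ts.label)


def _infer_fs(time_col: np.ndarray) -> float:
    if time_col.size < 2:
        raise SignalIOError("signal table needs at least two rows to infer fs")
    dt = np.diff(time_col)
    if np.any(dt <= 0):
        raise SignalIOError("time column must be strictly increasing")
    fs = (time_col.size - 1) / (time_col[-1] - time_col[0])
    # snap to the written rate: text-formatted times carry rounding noise
    snapped = round(fs) if abs(fs - round(fs)) < 1e-6 * fs else round(fs, 6)
    return float(snapped)


def write_signal_table(path, series: list[TimeSeries]) -> None:
    """Write channels sharing one clock as a delimited text table."""
    if not series:
        raise SignalError("no channels to write")
    first = series[0]
    for ts in series[1:]:
        if ts.fs != first.fs or ts.t0 != first.t0 or len(ts) != len(first):
            raise SignalError("all channels must share fs, t0 and length")
    data = {"time_s": first.times}
    for ts in series:
        if not ts.label:
            raise SignalError("every channel needs a label to be written")
        data[ts.label] = ts.samples
    pd.DataFrame(data).to_csv(path, index=False)


def read_signal_table(path, columns: list[str] | None = None) -> list[TimeSeries]:
    """Read a signal table back into one :class:`TimeSeries` per channel.

    ``columns`` selects (and orders) channels; default is every non-time
    column in file order.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message path
        raise SignalIOError(f"cannot parse signal table {path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise SignalIOError(f"signal table {path} lacks a 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    fs = _infer_fs(t)
    names = columns if columns is not None else [c for c in df.columns if c != "time_s"]
    out = []
    for name in names:
        if name not in df.columns:
            raise SignalIOError(f"channel {name!r} not in signal table {path}")
        out.append(TimeSeries(df[name].to_numpy(dtype=float), fs, float(t[0]), name))
    if not out:
        raise SignalIOError(f"signal table {path} has no channel columns")
    return out


def write_annotations(path, ann: EventAnnotations) -> None:
    pd.DataFrame(ann.events, columns=["time_s", "label"]).to_csv(path, index=False)


def read_annotations(path) -> EventAnnotations:
    """Read a ``time_s,label`` annotation table."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message path
        raise SignalIOError(f"cannot parse annotations {path}: {exc}") from exc
    for col in ("time_s", "label"):
        if col not in df.columns:
            raise SignalIOError(f"annotation file {path} lacks column {col!r}")
    events = [(float(t), str(lab)) for t, lab in zip(df["time_s"], df["label"])]
    try:
        return EventAnnotations(events)
    except SignalError as exc:
        raise SignalIOError(f"annotation file {path}: {exc}") from exc
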