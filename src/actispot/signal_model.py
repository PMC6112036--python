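"""Core containers and I/O for wrist-worn inertial recordings.

A recording session is represented by one or more :class:`SensorStream`
objects (one per device, e.g. the left- and right-wrist accelerometer) plus
a list of :class:`LabelInterval` annotations.  Timestamps are integer
milliseconds since the start of the recording; at the 40–50 Hz rates of
wrist-worn devices sub-millisecond precision carries no information.

All intervals in the package — labels, slices, match candidates — are
half-open ``[start_ms, end_ms)`` so that abutting intervals do not overlap.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SensorStream",
    "LabelInterval",
    "Recording",
    "read_sensor_csv",
    "write_sensor_csv",
    "read_labels_csv",
    "write_labels_csv",
    "shift_stream",
    "slice_stream",
]

HANDS = ("left", "right", "both", "unknown")


class FormatError(ValueError):
    """Raised when an input file does not follow the expected schema."""


@dataclass
class SensorStream:
    """Timestamped multi-channel samples from a single device.

    Parameters
    ----------
    recording_id : str
        Identifier of the recording session the stream belongs to.
    device : str
        Device name, e.g. ``"wrist_right"``.
    sample_rate_hz : float
        Nominal sampling rate (40 Hz for the wristband class of devices;
        Android pushes sensor values, so actual spacing may jitter).
    timestamps : ndarray of int64
        Milliseconds since recording start, strictly increasing.
    channels : list of str
        Ordered channel names, e.g. ``["x", "y", "z"]``.
    values : ndarray, shape (n_samples, n_channels)
        One sample vector per timestamp, acceleration in m/s².
    """

    recording_id: str
    device: str
    sample_rate_hz: float
    timestamps: np.ndarray
    channels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.size == 0:
            self.values = self.values.reshape(0, len(self.channels))
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.timestamps.ndim != 1:
            raise ValueError("timestamps must be 1-D")
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise ValueError(
                f"{self.values.shape[0]} sample vectors for "
                f"{self.timestamps.shape[0]} timestamps"
            )
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"sample vectors of length {self.values.shape[1]} for "
                f"{len(self.channels)} channels"
            )
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.shape[0])

    @property
    def duration_ms(self) -> int:
        if self.n_samples == 0:
            return 0
        return int(self.timestamps[-1] - self.timestamps[0])

    def step_ms(self) -> float:
        """Median sample spacing in ms (robust to Android push jitter)."""
        if self.n_samples < 2:
            return 1000.0 / self.sample_rate_hz
        return float(np.median(np.diff(self.timestamps)))


@dataclass(frozen=True)
class LabelInterval:
    """A half-open annotated activity span ``[start_ms, end_ms)``."""

    start_ms: int
    end_ms: int
    label: str
    hand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start_ms >= self.end_ms:
            raise ValueError(
                f"label '{self.label}': start_ms {self.start_ms} must be < "
                f"end_ms {self.end_ms}"
            )
        if self.hand not in HANDS:
            raise ValueError(f"hand must be one of {HANDS}, got {self.hand!r}")

    @property
    def duration_ms(self) -> int:
        return self.end_ms - self.start_ms


@dataclass
class Recording:
    """One session: streams keyed by device name, annotations, metadata."""

    recording_id: str
    streams: dict[str, SensorStream] = field(default_factory=dict)
    labels: list[LabelInterval] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def primary_stream(self, device: str | None = None) -> SensorStream:
        if device is not None:
            return self.streams[device]
        return next(iter(self.streams.values()))


def read_sensor_csv(path: str | Path, device: str, sample_rate_hz: float) -> SensorStream:
    """Read one device's samples from CSV.

    The file needs a header row with a ``timestamp_ms`` column plus one or
    more numeric channel columns (channel names are free).  Rows are sorted
    by timestamp; duplicate timestamps keep the first occurrence.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "timestamp_ms" not in df.columns:
        raise FormatError(f"{path}: missing required column 'timestamp_ms'")
    channels = [c for c in df.columns if c != "timestamp_ms"]
    if not channels:
        raise FormatError(f"{path}: no channel columns besides timestamp_ms")
    for col in ["timestamp_ms", *channels]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.index[coerced.isna()][0]) + 2  # 1-based, after header
            raise FormatError(f"{path}: non-numeric value in column '{col}' at line {row}")
        df[col] = coerced
    df = df.sort_values("timestamp_ms", kind="stable")
    df = df.drop_duplicates(subset="timestamp_ms", keep="first")
    return SensorStream(
        recording_id=path.stem,
        device=device,
        sample_rate_hz=sample_rate_hz,
        timestamps=df["timestamp_ms"].to_numpy(dtype=np.int64),
        channels=channels,
        values=df[channels].to_numpy(dtype=np.float64),
    )


def write_sensor_csv(stream: SensorStream, path: str | Path) -> None:
    """Write a stream in the same dialect :func:`read_sensor_csv` reads."""
    df = pd.DataFrame(stream.values, columns=stream.channels)
    df.insert(0, "timestamp_ms", stream.timestamps)
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def read_labels_csv(path: str | Path) -> list[LabelInterval]:
    """Read annotation intervals; columns ``start_ms,end_ms,label[,hand]``."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"start_ms", "end_ms", "label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    labels = []
    for i, row in df.iterrows():
        hand = "unknown"
        if "hand" in df.columns and not pd.isna(row["hand"]):
            hand = str(row["hand"])
        try:
            labels.append(
                LabelInterval(int(row["start_ms"]), int(row["end_ms"]),
                              str(row["label"]), hand)
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    labels.sort(key=lambda lab: (lab.start_ms, lab.end_ms))
    return labels


def write_labels_csv(labels: list[LabelInterval], path: str | Path) -> None:
    df = pd.DataFrame(
        [(lab.start_ms, lab.end_ms, lab.label, lab.hand) for lab in labels],
        columns=["start_ms", "end_ms", "label", "hand"],
    )
    df.to_csv(path, index=False, lineterminator="\n")


def shift_stream(stream: SensorStream, offset_ms: int) -> SensorStream:
    """Shift all timestamps by a constant offset (may produce negatives).

    This is the programmatic half of cross-device alignment: the reference
    moment (e.g. an idle-to-walk transition visible on all devices) is
    located externally and the resulting constant offset applied here.
    """
    return replace(stream, timestamps=stream.timestamps + int(offset_ms))


def slice_stream(stream: SensorStream, start_ms: int, end_ms: int) -> SensorStream:
    """Samples with ``start_ms <= t < end_ms``; may be empty."""
    if start_ms >= end_ms:
        raise ValueError(f"slice start {start_ms} must be < end {end_ms}")
    mask = (stream.timestamps >= start_ms) & (stream.timestamps < end_ms)
    return replace(stream, timestamps=stream.timestamps[mask], values=stream.values[mask])
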