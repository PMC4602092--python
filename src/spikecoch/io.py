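"""Waveform, AER event-stream and matrix I/O.

Conventions fixed here so the rest of the package is format-agnostic:

* Audio is mono float64 in [-1, 1]; stereo files are averaged to mono on read.
* Address-event (AER) streams are stored in a plain-text CSV dialect with
  columns ``timestamp_us,channel,neuron,ear``.  Channel 1 is the lowest
  frequency; hardware cascade order (highest best-characteristic-frequency
  first) is converted on read of the raw ``jaer-text`` dialect.
* Timestamps are microseconds from stimulus onset and are never re-zeroed;
  binning operations take an explicit origin.
* 2-D matrices travel in HDF5 with their axis metadata as attributes, so
  round-trips are lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

EARS = ("left", "right")

_EVENT_COLUMNS = ["timestamp_us", "channel", "neuron", "ear"]


@dataclass
class AudioSignal:
    """A mono waveform with its sampling rate in Hz."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if not np.isfinite(self.sample_rate) or self.sample_rate <= 0:
            raise ValidationError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValidationError("audio samples must be finite")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class EventStream:
    """Timestamped address events from a spiking cochlea.

    ``channel`` is 1..n_channels ascending in frequency, ``neuron`` 1..4
    (the four ganglion cells per channel), ``ear`` in {"left", "right"}.
    """

    timestamp_us: np.ndarray
    channel: np.ndarray
    neuron: np.ndarray
    ear: np.ndarray
    source: str = "software"
    n_channels: int = 64

    def __post_init__(self) -> None:
        self.timestamp_us = np.asarray(self.timestamp_us, dtype=np.int64)
        self.channel = np.asarray(self.channel, dtype=np.int64)
        self.neuron = np.asarray(self.neuron, dtype=np.int64)
        self.ear = np.asarray(self.ear, dtype="U5")
        n = len(self.timestamp_us)
        for name in ("channel", "neuron", "ear"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"field {name!r} length mismatch")
        if n:
            if np.any(np.diff(self.timestamp_us) < 0):
                raise ValidationError("timestamps must be non-decreasing")
            self._check_ranges()

    def _check_ranges(self) -> None:
        bad = np.flatnonzero((self.channel < 1) | (self.channel > self.n_channels))
        if bad.size:
            raise ValidationError(
                f"channel {self.channel[bad[0]]} outside [1, {self.n_channels}] at event {bad[0]}"
            )
        bad = np.flatnonzero((self.neuron < 1) | (self.neuron > 4))
        if bad.size:
            raise ValidationError(f"neuron {self.neuron[bad[0]]} outside [1, 4] at event {bad[0]}")
        bad = np.flatnonzero(~np.isin(self.ear, EARS))
        if bad.size:
            raise ValidationError(f"ear {self.ear[bad[0]]!r} not in {EARS} at event {bad[0]}")

    def __len__(self) -> int:
        return len(self.timestamp_us)


def read_wav(path) -> AudioSignal:
    """Read a PCM or float WAV file as mono float64 in [-1, 1]."""
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"unreadable WAV file {path}: {exc}") from exc
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"unsupported WAV sample format {data.dtype} in {path}")
    if samples.ndim == 2:  # stereo -> mono
        samples = samples.mean(axis=1)
    return AudioSignal(samples, float(rate))


def write_wav(path, audio: AudioSignal, dtype: str = "int16") -> None:
    """Write an :class:`AudioSignal` as 16-bit PCM (default) or float32 WAV."""
    x = np.clip(audio.samples, -1.0, 1.0)
    if dtype == "int16":
        wavfile.write(path, int(round(audio.sample_rate)), np.round(x * 32767).astype(np.int16))
    elif dtype == "float32":
        wavfile.write(path, int(round(audio.sample_rate)), x.astype(np.float32))
    else:
        raise ValidationError(f"dtype must be 'int16' or 'float32', got {dtype!r}")


def _decode_jaer_address(address: np.ndarray, n_channels: int):
    """Split a raw jAER-style address word into (channel, neuron, ear).

    Bit layout: bit 0 = ear, bits 1-2 = neuron index, bits 3+ = cascade
    position (0 = highest best characteristic frequency).  Cascade order is
    converted so channel 1 is the lowest frequency.
    """
    ear = np.where(address & 1, "right", "left")
    neuron = ((address >> 1) & 0b11) + 1
    cascade_pos = address >> 3
    channel = n_channels - cascade_pos
    return channel, neuron, ear


def read_events(path, dialect: str = "csv", n_channels: int = 64, source: str | None = None) -> EventStream:
    """Read an AER event stream.

    ``dialect`` is ``"csv"`` (columns ``timestamp_us,channel,neuron,ear``) or
    ``"jaer-text"`` (whitespace-separated ``timestamp address`` lines, hardware
    address layout).  Out-of-order events are stably sorted with a warning.
    """
    if dialect not in ("csv", "jaer-text"):
        raise ValidationError(f"dialect must be 'csv' or 'jaer-text', got {dialect!r}")
    if dialect == "csv":
        try:
            table = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            table = pd.DataFrame(columns=_EVENT_COLUMNS)
        missing = [c for c in _EVENT_COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        ts = table["timestamp_us"].to_numpy(dtype=np.int64)
        channel = table["channel"].to_numpy(dtype=np.int64)
        neuron = table["neuron"].to_numpy(dtype=np.int64)
        ear = table["ear"].astype(str).to_numpy()
        src = source or "software"
    else:
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(f"{path}:{lineno}: expected 'timestamp address'")
                rows.append((int(parts[0]), int(parts[1])))
        arr = np.array(rows, dtype=np.int64).reshape(-1, 2)
        ts = arr[:, 0]
        channel, neuron, ear = _decode_jaer_address(arr[:, 1], n_channels)
        src = source or "hardware"

    _validate_event_ranges(channel, neuron, ear, n_channels, path)
    if ts.size and np.any(np.diff(ts) < 0):
        log.warning("%s: events out of order; applying stable sort", path)
        order = np.argsort(ts, kind="stable")
        ts, channel, neuron, ear = ts[order], channel[order], neuron[order], ear[order]
    return EventStream(ts, channel, neuron, ear, source=src, n_channels=n_channels)


def _validate_event_ranges(channel, neuron, ear, n_channels, path) -> None:
    # line numbers: header line + 1-based data rows for the CSV dialect
    bad = np.flatnonzero((channel < 1) | (channel > n_channels))
    if bad.size:
        raise ValidationError(
            f"{path}: channel {channel[bad[0]]} outside [1, {n_channels}] (data line {bad[0] + 1})"
        )
    bad = np.flatnonzero((neuron < 1) | (neuron > 4))
    if bad.size:
        raise ValidationError(f"{path}: neuron {neuron[bad[0]]} outside [1, 4] (data line {bad[0] + 1})")
    bad = np.flatnonzero(~np.isin(np.asarray(ear, dtype="U5"), EARS))
    if bad.size:
        raise ValidationError(f"{path}: ear {ear[bad[0]]!r} invalid (data line {bad[0] + 1})")


def write_events(path, stream: EventStream) -> None:
    """Write an event stream in the canonical CSV dialect."""
    pd.DataFrame(
        {
            "timestamp_us": stream.timestamp_us,
            "channel": stream.channel,
            "neuron": stream.neuron,
            "ear": stream.ear,
        }
    ).to_csv(path, index=False)


def write_matrix(path, matrix: np.ndarray, axis_metadata: dict) -> None:
    """Write a 2-D matrix plus axis metadata to HDF5 (lossless round-trip)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2:
        raise ValidationError(f"matrix must be 2-D, got shape {matrix.shape}")
    if matrix.size and not np.all(np.isfinite(matrix)):
        raise ValidationError("matrix contains NaN/inf entries")
    with h5py.File(path, "w") as fh:
        dset = fh.create_dataset("values", data=matrix)
        for key, value in axis_metadata.items():
            dset.attrs[key] = value


def read_matrix(path):
    """Read a matrix written by :func:`write_matrix`; returns (values, metadata)."""
    with h5py.File(path, "r") as fh:
        if "values" not in fh:
            raise FormatError(f"{path}: missing 'values' dataset")
        dset = fh["values"]
        values = dset[()]
        meta = {}
        for key, value in dset.attrs.items():
            if isinstance(value, bytes):
                value = value.decode()
            meta[key] = value
    return values, meta
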