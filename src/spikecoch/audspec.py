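"""Auditory spectrogram: 128-channel log-frequency, 10 ms-frame representation.

The target representation for decoding mimics early auditory-nerve responses:
the waveform (resampled to 16 kHz) is passed through a bank of constant-Q
bandpass filters whose center frequencies form a geometric progression over
180-7246 Hz, half-wave rectified, leaky-integrated with a 10 ms time constant,
and sampled once per 10 ms frame.  Adjacent channels are separated by a
constant ratio of about 1.029 (so channel 10 sits near 240 Hz, channel 40 near
571 Hz and channel 60 near 1017.5 Hz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy import signal

from .errors import ValidationError
from .io import AudioSignal

log = logging.getLogger(__name__)

SAMPLE_RATE = 16000.0  # Hz, analysis rate after resampling
N_CHANNELS = 128
F_MIN = 180.0  # Hz
F_MAX = 7246.0  # Hz
FRAME_LENGTH = 0.010  # s
INTEGRATION_TC = 0.010  # s


def channel_frequency(
    f_index, n_channels: int = N_CHANNELS, f_min: float = F_MIN, f_max: float = F_MAX
):
    """Center frequency (Hz) of channel ``f_index`` on the geometric grid.

    ``f(k) = f_min * r**k`` with ``r = (f_max / f_min) ** (1 / n_channels)``;
    index 0 sits at ``f_min``, index ``n_channels`` at ``f_max``.
    """
    if f_min >= f_max:
        raise ValidationError(f"f_min ({f_min}) must be below f_max ({f_max})")
    if f_min <= 0:
        raise ValidationError("f_min must be positive")
    f_index = np.asarray(f_index)
    if np.any(f_index < 0) or np.any(f_index > n_channels):
        raise ValidationError(f"channel index must lie in [0, {n_channels}]")
    ratio = (f_max / f_min) ** (1.0 / n_channels)
    return f_min * ratio**f_index


@dataclass
class AuditorySpectrogram:
    """Non-negative time-frequency matrix ``values[t, f]`` on a 10 ms grid."""

    values: np.ndarray  # (n_frames, n_channels)
    frame_length: float = FRAME_LENGTH
    integration_tc: float = INTEGRATION_TC
    center_freqs: np.ndarray | None = None  # Hz, ascending geometric grid
    sample_rate_in: float = SAMPLE_RATE

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@lru_cache(maxsize=8)
def _filterbank(n_channels: int, f_min: float, f_max: float, fs: float):
    """Cached constant-Q bank: (center_freqs, list of sos arrays).

    Each channel is an order-2 Butterworth bandpass whose -3 dB edges sit at
    the geometric midpoints to its neighbours, so adjacent bands overlap there.
    """
    ratio = (f_max / f_min) ** (1.0 / n_channels)
    cf = f_min * ratio ** np.arange(n_channels)
    half = np.sqrt(ratio)
    bank = []
    for f in cf:
        lo, hi = f / half, min(f * half, fs / 2 * 0.999)
        bank.append(signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos"))
    return cf, bank


def _resample(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    if abs(rate_in - rate_out) < 1e-9:
        return x
    frac = Fraction(rate_out / rate_in).limit_denominator(1000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def _subbands(x: np.ndarray, bank) -> np.ndarray:
    out = np.empty((len(bank), len(x)))
    for c, sos in enumerate(bank):
        out[c] = signal.sosfilt(sos, x)
    return out


def _envelopes(subbands: np.ndarray, fs: float, tc: float) -> np.ndarray:
    """Half-wave rectification followed by first-order leaky integration."""
    rect = np.maximum(subbands, 0.0)
    alpha = np.exp(-1.0 / (fs * tc))
    return signal.lfilter([1.0 - alpha], [1.0, -alpha], rect, axis=-1)


def _frame_sample_indices(n_samples: int, fs: float, frame_length: float) -> np.ndarray:
    step = int(round(fs * frame_length))
    n_frames = n_samples // step
    return (np.arange(n_frames) + 1) * step - 1


def audspec(
    audio: AudioSignal,
    n_channels: int = N_CHANNELS,
    f_min: float = F_MIN,
    f_max: float = F_MAX,
    frame_length: float = FRAME_LENGTH,
    integration_tc: float = INTEGRATION_TC,
    compression: str | None = None,
) -> AuditorySpectrogram:
    """Compute the auditory spectrogram of a waveform.

    Any input rate is accepted; the signal is polyphase-resampled to 16 kHz
    first.  Frame ``t`` covers the half-open interval [t*10 ms, (t+1)*10 ms);
    the envelope value at the final sample of each frame is reported.
    ``compression`` is ``None`` (default), ``"cuberoot"`` or ``"log"``.
    """
    x = _resample(audio.samples, audio.sample_rate, SAMPLE_RATE)
    cf, bank = _filterbank(n_channels, f_min, f_max, SAMPLE_RATE)
    idx = _frame_sample_indices(len(x), SAMPLE_RATE, frame_length)
    if idx.size == 0:
        log.warning("audio shorter than one %.0f ms frame; empty spectrogram", frame_length * 1e3)
        return AuditorySpectrogram(np.zeros((0, n_channels)), frame_length, integration_tc, cf)
    env = _envelopes(_subbands(x, bank), SAMPLE_RATE, integration_tc)
    values = env[:, idx].T.copy()
    if compression == "cuberoot":
        values = np.cbrt(values)
    elif compression == "log":
        values = np.log1p(values / (np.max(values) * 1e-4 + 1e-30))
    elif compression is not None:
        raise ValidationError(f"unknown compression {compression!r}")
    return AuditorySpectrogram(values, frame_length, integration_tc, cf)


def _values(S) -> np.ndarray:
    return np.asarray(S.values if hasattr(S, "values") else S, dtype=np.float64)


def spectrogram_correlation(S_a, S_b) -> float:
    """Pearson correlation between two equally shaped spectrograms.

    Returns NaN (with a warning) when either input has zero variance.
    """
    a, b = _values(S_a), _values(S_b)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    a, b = a.ravel(), b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        log.warning("zero-variance spectrogram; correlation undefined")
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
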