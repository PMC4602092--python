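"""Lyon-style cascade filterbank front end.

The software cochlea is a cascade of second-order notch/resonator sections
whose pole frequencies descend from just below Nyquist to the point where the
pole quality factor reaches 0.5.  The output tapped after each stage models
basilar-membrane motion at one cochlear place; half-wave rectification models
the inner hair cell, and the rectified values, globally rescaled to [0, 1],
are interpreted as per-sample firing probabilities (a "cochleagram").

Design equations follow the published Lyon/Slaney recipe: channel bandwidth
``B(f) = sqrt(f^2 + Eb^2) / Q_ear`` with ear break frequency ``Eb = 1 kHz``,
channel spacing proportional to ``step_factor * B(f)`` (i.e. uniform on the
asinh-warped frequency axis), pole Q ``f / B(f)`` saturating at ``Q_ear`` for
high frequencies, and a transfer-function zero ``step_factor * 1.5``
bandwidths above each pole.  The requested number of stages is placed
uniformly on the warped axis between the standard top and bottom frequencies,
so the default 64-stage design at 20 kHz spans roughly 63 Hz to 10 kHz.
Automatic gain control is deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import DesignError, ValidationError
from .io import AudioSignal

EAR_BREAK_FREQ = 1000.0  # Hz; corner of the bandwidth-vs-frequency law
EAR_ZERO_OFFSET = 1.5  # zero placed this many step-bandwidths above the pole
EAR_SHARPNESS = 5.0  # quality factor of the transfer-function zeros

DEFAULT_N_CHANNELS = 64
DEFAULT_EAR_Q = 8.0
DEFAULT_STEP_FACTOR = 0.25
DEFAULT_SAMPLE_RATE = 20000.0


def ear_bandwidth(freq, ear_q: float = DEFAULT_EAR_Q):
    """Channel bandwidth in Hz at center frequency ``freq``."""
    return np.sqrt(np.square(freq) + EAR_BREAK_FREQ**2) / ear_q


@dataclass(frozen=True)
class FilterbankDesign:
    """A designed cascade: one biquad per channel, highest frequency first."""

    n_channels: int
    ear_q: float
    step_factor: float
    sample_rate: float
    center_freqs: np.ndarray  # Hz, descending along the cascade
    sos: np.ndarray  # (n_channels, 6) second-order sections
    agc_enabled: bool = False

    @property
    def center_freqs_ascending(self) -> np.ndarray:
        return self.center_freqs[::-1]


def _biquad_half(freq, q, sample_rate):
    """[1, a1, a2] polynomial with resonance at ``freq`` and quality ``q``."""
    cft = freq / sample_rate
    rho = np.exp(-np.pi * cft / q)
    theta = 2 * np.pi * cft * np.sqrt(np.maximum(0.0, 1.0 - 1.0 / (4.0 * q**2)))
    return np.stack([np.ones_like(rho), -2 * rho * np.cos(theta), rho**2], axis=-1)


def design_filterbank(
    n_channels: int = DEFAULT_N_CHANNELS,
    ear_q: float = DEFAULT_EAR_Q,
    step_factor: float = DEFAULT_STEP_FACTOR,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> FilterbankDesign:
    """Design the cascade of second-order sections.

    Stages are spaced uniformly on the asinh-warped axis
    ``a(f) = ln(f + sqrt(f^2 + Eb^2))`` (the axis on which a constant step
    corresponds to ``step_factor`` bandwidths) between the standard top
    frequency (Nyquist minus first-zero headroom) and the frequency where the
    pole Q falls to 0.5.
    """
    if n_channels < 2:
        raise ValidationError(f"n_channels must be >= 2, got {n_channels}")
    if sample_rate <= 0:
        raise ValidationError(f"sample_rate must be positive, got {sample_rate}")
    if ear_q <= 0.5 or step_factor <= 0:
        raise ValidationError("ear_q must exceed 0.5 and step_factor must be positive")

    nyquist = sample_rate / 2.0
    step_bw = ear_bandwidth(nyquist, ear_q) * step_factor
    top = nyquist - step_bw * EAR_ZERO_OFFSET + step_bw
    low = EAR_BREAK_FREQ / np.sqrt(4.0 * ear_q**2 - 1.0)  # pole Q = 0.5 here

    def warp(f):
        return np.log(f + np.hypot(f, EAR_BREAK_FREQ))

    a = np.linspace(warp(top), warp(low), n_channels)
    center_freqs = (np.exp(a) - EAR_BREAK_FREQ**2 * np.exp(-a)) / 2.0

    bw = ear_bandwidth(center_freqs, ear_q)
    pole_q = np.maximum(center_freqs / bw, 0.5)
    zero_cf = np.minimum(center_freqs + bw * step_factor * EAR_ZERO_OFFSET, nyquist * 0.9999)

    num = _biquad_half(zero_cf, EAR_SHARPNESS, sample_rate)
    den = _biquad_half(center_freqs, pole_q, sample_rate)
    # unity gain at DC per stage
    num *= (den.sum(axis=1) / num.sum(axis=1))[:, None]

    sos = np.concatenate([num, den], axis=1)
    for stage in range(n_channels):
        poles = np.roots(den[stage])
        if np.any(np.abs(poles) >= 1.0):
            raise DesignError(
                f"stage {stage} (center {center_freqs[stage]:.1f} Hz) is unstable"
            )
    return FilterbankDesign(n_channels, float(ear_q), float(step_factor), float(sample_rate), center_freqs, sos)


@dataclass
class Cochleagram:
    """Per-channel firing probabilities at audio rate.

    ``values[t, m]`` is the probability of a spike in channel ``m`` (ascending
    in frequency) during sample-wide time bin ``t`` of width ``1/sample_rate``.
    ``gain`` is the global scale applied to the rectified cascade outputs, kept
    so the mapping to probabilities is invertible and reportable.
    """

    values: np.ndarray  # (T, n_channels), in [0, 1]
    sample_rate: float
    center_freqs: np.ndarray  # Hz, ascending
    gain: float = 1.0

    @property
    def bin_width(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def cascade_outputs(audio: AudioSignal, design: FilterbankDesign) -> np.ndarray:
    """Raw half-wave-rectified cascade outputs, shape (T, n_channels) ascending.

    This is the cochleagram before probability normalization; useful when the
    unscaled (linear-filter + rectifier) response is wanted.
    """
    if abs(audio.sample_rate - design.sample_rate) > 1e-9:
        raise ValidationError(
            f"audio rate {audio.sample_rate} Hz != design rate {design.sample_rate} Hz"
        )
    x = audio.samples
    out = np.empty((len(x), design.n_channels))
    for stage in range(design.n_channels):
        b, a = design.sos[stage, :3], design.sos[stage, 3:]
        x = signal.lfilter(b, a, x)
        out[:, stage] = x
    np.maximum(out, 0.0, out=out)  # inner-hair-cell rectification
    return out[:, ::-1]  # cascade order (high->low) to ascending frequency


def cochleagram(
    audio: AudioSignal,
    design: FilterbankDesign | None = None,
    p_max: float = 0.5,
    percentile: float = 99.9,
) -> Cochleagram:
    """Compute the cochleagram of ``audio``.

    The rectified cascade outputs are scaled by one global gain per recording
    so that the ``percentile``-th percentile maps to ``p_max``, then clipped to
    [0, 1].  ``p_max`` defaults to 0.5 to keep per-sample Bernoulli rates
    sub-saturating at audio rate.
    """
    if design is None:
        design = design_filterbank(sample_rate=audio.sample_rate)
    rect = cascade_outputs(audio, design)
    if rect.size:
        ref = np.percentile(rect, percentile)
    else:
        ref = 0.0
    gain = p_max / ref if ref > 0 else 1.0
    values = np.clip(rect * gain, 0.0, 1.0)
    return Cochleagram(values, design.sample_rate, design.center_freqs_ascending.copy(), gain)
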