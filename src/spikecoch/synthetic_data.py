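"""Synthetic stimuli and fixtures: digit-like tokens, babble, linear pairs.

Every pipeline stage is testable without downloading any corpus.  Spoken-digit
stand-ins are formant-modulated harmonic tokens: a jittered glottal impulse
train filtered through time-varying second-order formant resonators under an
attack/sustain/release envelope.  Classes are defined by their (F1, F2)
formant targets on a grid chosen so classes are pairwise separable by
construction; per-exemplar jitter of the fundamental (+-10%) and formants
(+-5%) emulates speaker variability.  Babble is the normalized sum of several
independent token streams.  ``linear_pair_fixture`` builds spike/spectrogram
pairs with exactly known lagged-linear structure, providing a ground-truth
oracle for decoder fitting.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import signal

from .audspec import AuditorySpectrogram
from .errors import ValidationError
from .io import AudioSignal
from .reconstruction import lagged_design
from .spikes import BinnedSpikegram

SAMPLE_RATE = 16000.0


@dataclass(frozen=True)
class FormantTrack:
    """One formant resonance: linear glide from start to end center frequency."""

    start_hz: float
    end_hz: float
    bandwidth_hz: float = 90.0


@dataclass(frozen=True)
class TokenSpec:
    """Full recipe for one synthetic token; deterministic given ``seed``."""

    class_label: str
    f0: float  # Hz, fundamental
    formants: tuple  # of FormantTrack
    duration: float = 0.5  # s
    attack: float = 0.03  # s
    release: float = 0.05  # s
    jitter: float = 0.01  # fractional period jitter of the glottal source
    seed: int = 0


class LabelledToken(NamedTuple):
    audio: AudioSignal
    label: str
    spec: TokenSpec


def _resonator_coeffs(freq: float, bandwidth: float, fs: float):
    rho = np.exp(-np.pi * bandwidth / fs)
    theta = 2 * np.pi * freq / fs
    b = np.array([1.0 - rho])
    a = np.array([1.0, -2.0 * rho * np.cos(theta), rho**2])
    return b, a


def synth_token(spec: TokenSpec, sample_rate: float = SAMPLE_RATE) -> AudioSignal:
    """Render a token: jittered impulse train -> formant resonators -> envelope."""
    nyquist = sample_rate / 2.0
    if not 0.2 <= spec.duration <= 2.0:
        raise ValidationError(f"duration must lie in [0.2, 2] s, got {spec.duration}")
    for f in spec.formants:
        if max(f.start_hz, f.end_hz) >= 0.98 * nyquist:
            raise ValidationError(f"formant at {max(f.start_hz, f.end_hz):.0f} Hz exceeds Nyquist")
        if min(f.start_hz, f.end_hz) <= 90.0:
            raise ValidationError("formants must stay above 90 Hz")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * sample_rate))

    excitation = np.zeros(n)
    t = 0.0
    period = sample_rate / spec.f0
    while t < n:
        excitation[int(t)] = 1.0
        t += period * (1.0 + spec.jitter * rng.standard_normal())
    excitation += 2e-3 * rng.standard_normal(n)  # aspiration noise floor

    # block-wise time-varying resonators, 10 ms update, state carried across blocks
    block = int(round(0.010 * sample_rate))
    y = excitation
    for track in spec.formants:
        out = np.empty(n)
        zi = np.zeros(2)
        for start in range(0, n, block):
            stop = min(start + block, n)
            frac = (start + stop) / 2.0 / n
            freq = track.start_hz + (track.end_hz - track.start_hz) * frac
            b, a = _resonator_coeffs(freq, track.bandwidth_hz, sample_rate)
            out[start:stop], zi = signal.lfilter(b, a, y[start:stop], zi=zi)
        y = out

    env = np.ones(n)
    n_att = int(round(spec.attack * sample_rate))
    n_rel = int(round(spec.release * sample_rate))
    if n_att:
        env[:n_att] = np.linspace(0.0, 1.0, n_att)
    if n_rel:
        env[-n_rel:] = np.linspace(1.0, 0.0, n_rel)
    y = y * env
    peak = np.max(np.abs(y))
    if peak > 0:
        y *= 0.9 / peak
    return AudioSignal(y, sample_rate)


# (F1, F2) grid giving well-separated vowel-like classes; F3 is shared.
_F1_GRID = (320.0, 470.0, 620.0, 770.0)
_F2_GRID = (1050.0, 1450.0, 1850.0, 2250.0)
_F3 = 2800.0


def _base_spec(class_index: int, label: str, seed: int) -> TokenSpec:
    f1 = _F1_GRID[class_index % len(_F1_GRID)]
    f2 = _F2_GRID[(class_index // len(_F1_GRID)) % len(_F2_GRID)]
    # small per-class formant glide makes trajectories, not just static spectra
    glide = 1.0 + 0.04 * ((class_index % 3) - 1)
    return TokenSpec(
        class_label=label,
        f0=110.0 + 10.0 * (class_index % 5),
        formants=(
            FormantTrack(f1, f1 * glide, 80.0),
            FormantTrack(f2, f2 / glide, 110.0),
            FormantTrack(_F3, _F3, 180.0),
        ),
        duration=0.45,
        seed=seed,
    )


def make_class_set(n_classes: int, n_per_class: int, seed: int = 0) -> list[LabelledToken]:
    """Generate a labelled token collection with pairwise-separable classes.

    Exemplars within a class jitter the fundamental by +-10% and formant
    centers by +-5% around the class base spec.
    """
    if n_classes < 2:
        raise ValidationError("need at least 2 classes")
    if n_classes > len(_F1_GRID) * len(_F2_GRID):
        raise ValidationError(f"at most {len(_F1_GRID) * len(_F2_GRID)} classes supported")
    root = np.random.default_rng(seed)
    tokens = []
    for c in range(n_classes):
        label = f"c{c:02d}"
        for e in range(n_per_class):
            token_seed = int(root.integers(0, 2**31 - 1))
            jit = np.random.default_rng(token_seed)
            base = _base_spec(c, label, token_seed)
            formants = tuple(
                FormantTrack(
                    f.start_hz * (1.0 + 0.05 * jit.uniform(-1, 1)),
                    f.end_hz * (1.0 + 0.05 * jit.uniform(-1, 1)),
                    f.bandwidth_hz,
                )
                for f in base.formants
            )
            spec = TokenSpec(
                class_label=label,
                f0=base.f0 * (1.0 + 0.10 * jit.uniform(-1, 1)),
                formants=formants,
                duration=base.duration,
                seed=token_seed,
            )
            tokens.append(LabelledToken(synth_token(spec), label, spec))
    return tokens


def _random_spec(rng: np.random.Generator, duration: float) -> TokenSpec:
    return TokenSpec(
        class_label="babble",
        f0=float(rng.uniform(85.0, 240.0)),
        formants=(
            FormantTrack(float(rng.uniform(300, 800)), float(rng.uniform(300, 800)), 90.0),
            FormantTrack(float(rng.uniform(950, 2400)), float(rng.uniform(950, 2400)), 120.0),
            FormantTrack(float(rng.uniform(2500, 3200)), float(rng.uniform(2500, 3200)), 200.0),
        ),
        duration=duration,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def babble_noise(duration: float, n_talkers: int = 8, seed: int = 0) -> AudioSignal:
    """Babble-like masker: normalized sum of independent token streams."""
    if n_talkers < 2:
        raise ValidationError("need at least 2 talkers")
    if duration <= 0:
        raise ValidationError("duration must be positive")
    n = int(round(duration * SAMPLE_RATE))
    root = np.random.default_rng(seed)
    total = np.zeros(n)
    for _ in range(n_talkers):
        talker = np.random.default_rng(int(root.integers(0, 2**31 - 1)))
        stream = np.zeros(0)
        while len(stream) < n:
            tok = synth_token(_random_spec(talker, float(talker.uniform(0.2, 0.4))))
            gap = np.zeros(int(talker.uniform(0, 0.05) * SAMPLE_RATE))
            stream = np.concatenate([stream, tok.samples, gap])
        total += stream[:n]
    total /= np.sqrt(n_talkers)
    peak = np.max(np.abs(total))
    if peak > 0:
        total *= 0.9 / peak
    return AudioSignal(total, SAMPLE_RATE)


def linear_pair_fixture(
    T: int,
    m: int,
    L: int,
    noise_snr_db: float = np.inf,
    seed: int = 0,
    n_freq: int = 128,
    rate: float = 2.0,
):
    """Spike/spectrogram pair with exactly known lagged-linear structure.

    ``R`` is i.i.d. Poisson counts (10 ms bins aggregate many near-Bernoulli
    draws, so counts are the right semantics); ``S`` is the lagged-linear
    image of ``R`` under a random known filter ``g`` plus Gaussian noise at
    ``noise_snr_db`` (infinity for noiseless).  Returns
    (BinnedSpikegram, AuditorySpectrogram, g) with g of shape
    (n_freq, 2L+1, m).
    """
    if T <= 2 * L + 1:
        raise ValidationError("need T > 2L+1 frames")
    rng = np.random.default_rng(seed)
    R = rng.poisson(rate, size=(T, m)).astype(np.float64)
    g = rng.standard_normal((n_freq, 2 * L + 1, m)) / np.sqrt((2 * L + 1) * m)
    W = g.transpose(1, 2, 0).reshape((2 * L + 1) * m, n_freq)
    S = lagged_design(R, L) @ W
    if np.isfinite(noise_snr_db):
        p_signal = np.mean(S**2)
        sigma = np.sqrt(p_signal * 10.0 ** (-noise_snr_db / 10.0))
        S = S + sigma * rng.standard_normal(S.shape)
    return (
        BinnedSpikegram(R, bin_width=0.010),
        AuditorySpectrogram(S, frame_length=0.010),
        g,
    )
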