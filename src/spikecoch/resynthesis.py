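"""Waveform resynthesis from an auditory spectrogram by iterative projection.

The auditory spectrogram discards phase, so inversion is iterative: starting
from Gaussian white noise, the current signal is analyzed with the same
filterbank/rectifier/integrator chain that produced the target, each subband
is rescaled by the ratio of target to current envelope, and the subbands are
re-summed.  Alternating between the signal domain and the spectrogram
constraint converges to a waveform whose auditory spectrogram approximates
the target; the early-stage non-linearity makes exact inversion impossible.

Because the 128 constant-Q bands overlap heavily, the rescaled subbands are
projected back into the signal domain through the adjoint of the analysis
filterbank (time-reversed filtering), which makes the effective per-channel
round-trip response zero-phase; naive re-summation lets differently phased
neighbouring subbands cancel and stalls the iteration.  Envelope ratios are
clipped to [0.1, 10] per iteration so near-silent subbands cannot blow up and
are linearly interpolated between 10 ms frame centers before being applied at
audio rate.  The iterate with the smallest spectrogram distance seen so far
is the one returned, scale-matched to the target (peak normalization for
listening happens at WAV-writing time, since the auditory spectrogram is
homogeneous and rescaling would break the distance guarantee).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .audspec import (F_MAX, F_MIN, FRAME_LENGTH, INTEGRATION_TC, SAMPLE_RATE,
                      _envelopes, _filterbank, _frame_sample_indices, _subbands)
from .errors import ValidationError
from .io import AudioSignal

DEFAULT_MAX_ITER = 200
DEFAULT_TOL = 1e-4  # relative distance improvement below which we stop
RATIO_BOUNDS = (0.1, 10.0)
DAMPING = 1.0  # optional exponent (<1) to damp the multiplicative update
_EPS = 1e-12


@dataclass
class InversionResult:
    """Inverted waveform plus the per-iteration spectrogram distance trace."""

    audio: AudioSignal
    iterations_run: int
    distances: np.ndarray  # relative Frobenius distance per iteration
    seed: int


def invert_spectrogram(
    S_target,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
    ratio_bounds: tuple = RATIO_BOUNDS,
    damping: float = DAMPING,
    f_min: float = F_MIN,
    f_max: float = F_MAX,
) -> InversionResult:
    """Invert an auditory spectrogram to a 16 kHz waveform.

    Negative target entries (possible decoder output) are clipped to zero.
    Iteration stops after ``max_iter`` rounds or when the relative improvement
    of the spectrogram distance falls below ``tol``.  The returned audio is
    the best iterate, on the amplitude scale implied by the target.
    """
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")
    values = np.asarray(S_target.values if hasattr(S_target, "values") else S_target, dtype=np.float64)
    if values.ndim != 2:
        raise ValidationError(f"target must be 2-D, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValidationError("target spectrogram contains NaN/inf")
    target = np.clip(values, 0.0, None)
    n_frames, n_channels = target.shape
    fs = SAMPLE_RATE
    step = int(round(fs * FRAME_LENGTH))
    n_samples = n_frames * step
    _, bank = _filterbank(n_channels, f_min, f_max, fs)
    frame_idx = _frame_sample_indices(n_samples, fs, FRAME_LENGTH)
    frame_centers = (np.arange(n_frames) + 0.5) * step
    sample_grid = np.arange(n_samples)

    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_samples) * 0.01
    target_norm = np.linalg.norm(target)
    distances = []
    lo, hi = ratio_bounds
    best_x, best_dist = x, np.inf

    for _ in range(max_iter):
        sub = _subbands(x, bank)
        env = _envelopes(sub, fs, INTEGRATION_TC)
        S_cur = env[:, frame_idx].T  # (n_frames, n_channels)
        dist = np.linalg.norm(S_cur - target) / max(target_norm, _EPS)
        distances.append(dist)
        if dist < best_dist:
            best_x, best_dist = x, dist
        if len(distances) > 1:
            improvement = distances[-2] - dist
            if improvement < tol * max(distances[-2], _EPS):
                break
        ratio = np.clip(target / (S_cur + _EPS), lo, hi)
        if damping != 1.0:
            ratio **= damping
        # rescale each subband and project back through the adjoint filterbank
        x_new = np.zeros(n_samples)
        for c in range(n_channels):
            ratio_up = np.interp(sample_grid, frame_centers, ratio[:, c])
            scaled = sub[c] * ratio_up
            x_new += signal.sosfilt(bank[c], scaled[::-1])[::-1]
        x = x_new

    x = best_x
    return InversionResult(
        audio=AudioSignal(x, fs),
        iterations_run=len(distances),
        distances=np.asarray(distances),
        seed=seed,
    )
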