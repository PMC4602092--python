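"""Evaluation: SNR mixing, STOI intelligibility, and digit-style classification.

The classification stage emulates a matched/mismatched word-recognition
protocol: utterances are represented by 39-dimensional MFCC feature vectors
(13 cepstra + deltas + accelerations, 25 ms windows, 10 ms hop) and classified
by a deterministic segmental template model — each class is summarized by a
fixed number of temporal segments, each a diagonal-covariance Gaussian over
the frames falling in that segment.  Training on one domain (e.g. original
audio) and testing on another (e.g. audio reconstructed from cochlea spikes)
probes how much the reconstruction changes the feature statistics.

STOI (short-time objective intelligibility) follows the published procedure:
10 kHz resampling, silent-frame removal, one-third-octave band energies from a
512-point STFT, and clipped, normalized envelope correlation over 386 ms
(30-frame) segments.

PESQ is an ITU-standardized metric and is not re-implemented; ``external_pesq``
shells out to a user-supplied command when one is available and degrades
gracefully otherwise.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.fft import dct, rfft

from .audspec import _resample
from .errors import ValidationError
from .io import AudioSignal

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# SNR mixing
# --------------------------------------------------------------------------

def mix_at_snr(
    sig: AudioSignal,
    noise: AudioSignal,
    snr_db: float,
    seed: int = 0,
    return_components: bool = False,
):
    """Add noise to ``sig`` at an exact signal-to-noise ratio in dB.

    The noise must be at least as long as the signal; a random (seeded) offset
    crops a matching segment, which is then scaled so that
    ``10*log10(P_signal / P_noise) == snr_db`` over the signal support.
    """
    if abs(sig.sample_rate - noise.sample_rate) > 1e-9:
        raise ValidationError("signal and noise sample rates differ")
    n = len(sig)
    if len(noise) < n:
        raise ValidationError("noise must be at least as long as the signal")
    rng = np.random.default_rng(seed)
    offset = int(rng.integers(0, len(noise) - n + 1))
    crop = noise.samples[offset : offset + n]
    p_sig = np.mean(sig.samples**2)
    p_noise = np.mean(crop**2)
    if p_sig == 0 or p_noise == 0:
        raise ValidationError("zero-power signal or noise segment")
    scale = np.sqrt(p_sig / p_noise * 10.0 ** (-snr_db / 10.0))
    scaled = crop * scale
    mixture = AudioSignal(sig.samples + scaled, sig.sample_rate)
    if return_components:
        return mixture, sig.samples.copy(), scaled
    return mixture


# --------------------------------------------------------------------------
# STOI
# --------------------------------------------------------------------------

_STOI_FS = 10000.0
_STOI_FRAME = 256
_STOI_HOP = 128
_STOI_NFFT = 512
_STOI_N_BANDS = 15
_STOI_MIN_FREQ = 150.0
_STOI_SEG = 30  # frames per segment (~386 ms)
_STOI_BETA = -15.0  # dB, lower signal-to-distortion bound
_STOI_DYN_RANGE = 40.0  # dB, silent-frame threshold below the loudest frame


def third_octave_bands(fs: float = _STOI_FS, nfft: int = _STOI_NFFT,
                       n_bands: int = _STOI_N_BANDS, min_freq: float = _STOI_MIN_FREQ):
    """One-third-octave band membership matrix over rfft bins; (n_bands, nfft//2+1)."""
    freqs = np.linspace(0.0, fs / 2.0, nfft // 2 + 1)
    k = np.arange(n_bands)
    f_low = min_freq * 2.0 ** ((2 * k - 1) / 6.0)
    f_high = min_freq * 2.0 ** ((2 * k + 1) / 6.0)
    obm = np.zeros((n_bands, len(freqs)))
    for j in range(n_bands):
        obm[j, (freqs >= f_low[j]) & (freqs < f_high[j])] = 1.0
    return obm


def _frame(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    n_frames = max(0, (len(x) - frame) // hop + 1)
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def _remove_silent_frames(x: np.ndarray, y: np.ndarray, dyn_range: float,
                          frame: int, hop: int):
    w = np.hanning(frame + 2)[1:-1]
    frames_x = _frame(x, frame, hop) * w
    frames_y = _frame(y, frame, hop) * w
    if not len(frames_x):
        return x[:0], y[:0]
    energies = 20.0 * np.log10(np.linalg.norm(frames_x, axis=1) + 1e-300)
    mask = energies > energies.max() - dyn_range
    frames_x, frames_y = frames_x[mask], frames_y[mask]
    n_kept = len(frames_x)
    out_len = (n_kept - 1) * hop + frame if n_kept else 0
    xs = np.zeros(out_len)
    ys = np.zeros(out_len)
    for i in range(n_kept):  # overlap-add with the same analysis window
        xs[i * hop : i * hop + frame] += frames_x[i]
        ys[i * hop : i * hop + frame] += frames_y[i]
    return xs, ys


def _band_envelopes(x: np.ndarray, obm: np.ndarray) -> np.ndarray:
    w = np.hanning(_STOI_FRAME + 2)[1:-1]
    frames = _frame(x, _STOI_FRAME, _STOI_HOP) * w
    spec = rfft(frames, n=_STOI_NFFT, axis=1)
    return np.sqrt(obm @ (np.abs(spec) ** 2).T)  # (n_bands, n_frames)


def stoi(clean: AudioSignal, degraded: AudioSignal) -> float:
    """Short-time objective intelligibility of ``degraded`` given ``clean``.

    Returns a score that is approximately in [0, 1] (perfect reproduction
    scores 1).  Inputs must share length and sample rate and last at least
    386 ms of non-silent speech.
    """
    if abs(clean.sample_rate - degraded.sample_rate) > 1e-9:
        raise ValidationError("clean and degraded sample rates differ")
    if len(clean) != len(degraded):
        raise ValidationError("clean and degraded must have equal length")
    min_dur = _STOI_SEG * _STOI_HOP / _STOI_FS  # 384 ms of analysis frames
    if clean.duration < min_dur:
        raise ValidationError(f"inputs must last at least {min_dur * 1e3:.0f} ms")
    x = _resample(clean.samples, clean.sample_rate, _STOI_FS)
    y = _resample(degraded.samples, degraded.sample_rate, _STOI_FS)
    x, y = _remove_silent_frames(x, y, _STOI_DYN_RANGE, _STOI_FRAME, _STOI_HOP)
    obm = third_octave_bands()
    X = _band_envelopes(x, obm)
    Y = _band_envelopes(y, obm)
    n_frames = X.shape[1]
    if n_frames < _STOI_SEG:
        raise ValidationError(
            f"fewer than {_STOI_SEG} non-silent frames; need >= 386 ms of speech"
        )
    clip = 10.0 ** (-_STOI_BETA / 20.0)
    scores = []
    for m in range(_STOI_SEG, n_frames + 1):
        xs = X[:, m - _STOI_SEG : m]
        ys = Y[:, m - _STOI_SEG : m]
        alpha = np.linalg.norm(xs, axis=1, keepdims=True) / (
            np.linalg.norm(ys, axis=1, keepdims=True) + 1e-300
        )
        ys_clipped = np.minimum(ys * alpha, xs * (1.0 + clip))
        xc = xs - xs.mean(axis=1, keepdims=True)
        yc = ys_clipped - ys_clipped.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(yc, axis=1) + 1e-300
        scores.append(np.sum(xc * yc, axis=1) / denom)
    return float(np.mean(scores))


def external_pesq(clean_path, degraded_path, command: str = "pesq") -> float | None:
    """Optional hook to an external PESQ binary; returns None when unavailable."""
    if shutil.which(command) is None:
        log.warning("external PESQ command %r not found; skipping", command)
        return None
    proc = subprocess.run(
        [command, "+16000", str(clean_path), str(degraded_path)],
        capture_output=True, text=True, check=False,
    )
    for token in reversed(proc.stdout.split()):
        try:
            return float(token)
        except ValueError:
            continue
    log.warning("could not parse PESQ output")
    return None


# --------------------------------------------------------------------------
# MFCC features
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureConfig:
    """MFCC front-end configuration (frozen into trained classifier models)."""

    sample_rate: float = 16000.0
    frame_length: float = 0.025
    hop: float = 0.010
    n_fft: int = 512
    n_mels: int = 26
    n_cepstra: int = 13
    preemphasis: float = 0.97
    delta_window: int = 2


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, fs: float) -> np.ndarray:
    """Triangular mel filterbank over rfft bins; (n_mels, n_fft//2 + 1)."""
    mel_points = np.linspace(_hz_to_mel(0.0), _hz_to_mel(fs / 2.0), n_mels + 2)
    hz_points = _mel_to_hz(mel_points)
    bins = np.floor((n_fft + 1) * hz_points / fs).astype(int)
    fb = np.zeros((n_mels, n_fft // 2 + 1))
    for j in range(1, n_mels + 1):
        left, center, right = bins[j - 1], bins[j], bins[j + 1]
        for k in range(left, center):
            if center > left:
                fb[j - 1, k] = (k - left) / (center - left)
        for k in range(center, right):
            if right > center:
                fb[j - 1, k] = (right - k) / (right - center)
    return fb


def _delta(feat: np.ndarray, window: int) -> np.ndarray:
    denom = 2.0 * sum(i * i for i in range(1, window + 1))
    padded = np.pad(feat, ((window, window), (0, 0)), mode="edge")
    out = np.zeros_like(feat)
    for i in range(1, window + 1):
        out += i * (padded[window + i : window + i + len(feat)] -
                    padded[window - i : window - i + len(feat)])
    return out / denom


def mfcc_features(audio: AudioSignal, config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """39-dimensional MFCC + delta + acceleration features, (n_frames, 39)."""
    x = _resample(audio.samples, audio.sample_rate, config.sample_rate)
    x = np.append(x[0], x[1:] - config.preemphasis * x[:-1])
    frame = int(round(config.frame_length * config.sample_rate))
    hop = int(round(config.hop * config.sample_rate))
    frames = _frame(x, frame, hop)
    if not len(frames):
        raise ValidationError("audio too short for a single analysis frame")
    frames = frames * np.hamming(frame)
    power = np.abs(rfft(frames, n=config.n_fft, axis=1)) ** 2
    fb = mel_filterbank(config.n_mels, config.n_fft, config.sample_rate)
    energies = np.log(np.maximum(power @ fb.T, 1e-12))
    cepstra = dct(energies, type=2, norm="ortho", axis=1)[:, : config.n_cepstra]
    d1 = _delta(cepstra, config.delta_window)
    d2 = _delta(d1, config.delta_window)
    return np.concatenate([cepstra, d1, d2], axis=1)


# --------------------------------------------------------------------------
# Segmental template classifier
# --------------------------------------------------------------------------

@dataclass
class ClassifierModel:
    """Per-class segmental diagonal-Gaussian templates over MFCC sequences."""

    class_labels: list
    means: np.ndarray  # (n_classes, n_segments, n_features)
    variances: np.ndarray  # same shape, floored
    feat_mean: np.ndarray  # global standardization
    feat_std: np.ndarray
    n_segments: int
    config: FeatureConfig
    seed: int


def _segment_bounds(n_frames: int, n_segments: int) -> np.ndarray:
    return np.linspace(0, n_frames, n_segments + 1).astype(int)


def _iter_pairs(dataset):
    for item in dataset:
        if hasattr(item, "audio") and hasattr(item, "label"):
            yield item.audio, item.label
        else:
            audio, label = item
            yield audio, label


def train_classifier(
    labelled_audio,
    seed: int = 0,
    n_segments: int = 5,
    config: FeatureConfig = FeatureConfig(),
    var_floor: float = 1e-2,
) -> ClassifierModel:
    """Train the segmental template classifier on (audio, label) pairs."""
    pairs = list(_iter_pairs(labelled_audio))
    labels = sorted({label for _, label in pairs})
    if len(labels) < 2:
        raise ValidationError("need at least 2 classes")
    counts = {lab: sum(1 for _, l in pairs if l == lab) for lab in labels}
    thin = [lab for lab, c in counts.items() if c < 2]
    if thin:
        raise ValidationError(f"need >= 2 exemplars per class; too few for {thin}")

    feats = [(mfcc_features(audio, config), label) for audio, label in pairs]
    stacked = np.vstack([f for f, _ in feats])
    feat_mean = stacked.mean(axis=0)
    feat_std = stacked.std(axis=0) + 1e-8

    n_feat = stacked.shape[1]
    means = np.zeros((len(labels), n_segments, n_feat))
    variances = np.ones_like(means)
    for ci, lab in enumerate(labels):
        seg_pool = [[] for _ in range(n_segments)]
        for f, l in feats:
            if l != lab:
                continue
            z = (f - feat_mean) / feat_std
            bounds = _segment_bounds(len(z), n_segments)
            for s in range(n_segments):
                seg_pool[s].append(z[bounds[s] : bounds[s + 1]])
        for s in range(n_segments):
            frames = np.vstack(seg_pool[s])
            means[ci, s] = frames.mean(axis=0)
            variances[ci, s] = frames.var(axis=0) + var_floor
    return ClassifierModel(labels, means, variances, feat_mean, feat_std,
                           n_segments, config, seed)


def classify(model: ClassifierModel, audio: AudioSignal) -> str:
    """Predict the class label of one utterance (deterministic argmax)."""
    z = (mfcc_features(audio, model.config) - model.feat_mean) / model.feat_std
    bounds = _segment_bounds(len(z), model.n_segments)
    scores = np.zeros(len(model.class_labels))
    for ci in range(len(model.class_labels)):
        ll = 0.0
        for s in range(model.n_segments):
            frames = z[bounds[s] : bounds[s + 1]]
            if not len(frames):
                continue
            mu, var = model.means[ci, s], model.variances[ci, s]
            diff = frames - mu
            ll += -0.5 * np.sum(diff**2 / var + np.log(2 * np.pi * var))
        scores[ci] = ll
    return model.class_labels[int(np.argmax(scores))]


def classification_accuracy(model: ClassifierModel, labelled_audio) -> float:
    """Fraction of utterances classified correctly, in [0, 1]."""
    pairs = list(_iter_pairs(labelled_audio))
    if not pairs:
        raise ValidationError("empty evaluation set")
    correct = sum(classify(model, audio) == label for audio, label in pairs)
    return correct / len(pairs)


# --------------------------------------------------------------------------
# Matched / mismatched protocol
# --------------------------------------------------------------------------

def matched_mismatch_protocol(
    domains: dict,
    labels,
    conditions,
    fraction: float = 0.5,
    seed: int = 0,
    n_segments: int = 5,
) -> pd.DataFrame:
    """Train/test accuracy over a (train domain x test domain) condition grid.

    ``domains`` maps a domain name (e.g. ``"original"``, ``"reconstructed"``,
    ``"noisy@-10dB"``) to a list of :class:`AudioSignal` aligned index-by-index
    with ``labels``; the same utterance-level split (seeded, stratified by
    label so every class keeps exemplars on both sides) is reused for all
    conditions so accuracies are comparable across the grid.
    """
    labels = list(labels)
    n = len(labels)
    bad = [name for name, sigs in domains.items() if len(sigs) != n]
    if bad:
        raise ValidationError(f"domains not aligned with labels: {bad}")
    rows = []
    if not conditions:
        return pd.DataFrame(columns=["train_domain", "test_domain", "n_train",
                                     "n_test", "n_correct", "accuracy", "seed"])
    from .reconstruction import train_test_split

    train_idx, test_idx = [], []
    for k, lab in enumerate(sorted(set(labels))):
        members = [i for i in range(n) if labels[i] == lab]
        tr, te = train_test_split(members, fraction=fraction, seed=seed + k)
        train_idx += tr
        test_idx += te
    for train_domain, test_domain in conditions:
        for name in (train_domain, test_domain):
            if name not in domains:
                raise ValidationError(f"unknown domain {name!r}")
        model = train_classifier(
            [(domains[train_domain][i], labels[i]) for i in train_idx],
            seed=seed, n_segments=n_segments,
        )
        n_correct = sum(
            classify(model, domains[test_domain][i]) == labels[i] for i in test_idx
        )
        rows.append(
            {
                "train_domain": train_domain,
                "test_domain": test_domain,
                "n_train": len(train_idx),
                "n_test": len(test_idx),
                "n_correct": int(n_correct),
                "accuracy": 100.0 * n_correct / len(test_idx),
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
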