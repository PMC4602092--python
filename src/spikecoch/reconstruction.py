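"""Optimal-prior linear decoding from binned spikegrams to auditory spectrograms.

The decoder is the MSE-optimal linear mapping

    S_hat_f(t) = sum_m sum_{tau=-L}^{L} g_f(tau, m) R(t - tau, m)

fitted independently per output frequency channel ``f`` by normalized reverse
correlation: the lagged spike autocorrelation matrix (pooled over training
utterances, zero-padded at utterance boundaries, never concatenated across
them) normalizes the spike-stimulus cross-correlation.  A ridge term expressed
as a fraction of the mean autocorrelation diagonal regularizes the solve; it
can also be chosen by generalized cross-validation.  Mean spike rates and the
mean stimulus spectrum are removed before fitting (each lagged regressor is
centered by its own mean, which equals the channel mean up to utterance-edge
effects) and the stimulus mean is restored on application.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.linalg

from .audspec import AuditorySpectrogram
from .errors import SolverError, ValidationError
from .spikes import BinnedSpikegram

log = logging.getLogger(__name__)

DEFAULT_LAG = 15  # time bins of context on each side
DEFAULT_RIDGE = 1e-3  # fraction of mean autocorrelation diagonal

_GCV_GRID = np.logspace(-7, 1, 17)


@dataclass
class DecoderFilter:
    """Fitted lagged linear mapping ``g_f(tau, m)``.

    ``weights`` has shape (n_freq, 2*lag + 1, n_channels); lag index 0
    corresponds to tau = -lag (future spikes relative to the frame being
    reconstructed come first).
    """

    weights: np.ndarray
    lag: int
    ridge_lambda: float | str
    ridge_effective: float
    bin_width: float
    x_mean: np.ndarray  # ((2*lag+1)*n_channels,) lagged-regressor means
    s_mean: np.ndarray  # (n_freq,)
    training_metadata: dict = field(default_factory=dict)

    @property
    def n_freq(self) -> int:
        return self.weights.shape[0]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[2]


def _as_matrix(obj) -> np.ndarray:
    values = obj.values if hasattr(obj, "values") else obj
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValidationError(f"expected a 2-D matrix, got shape {values.shape}")
    return values


def lagged_design(R: np.ndarray, lag: int) -> np.ndarray:
    """Design matrix with columns ``R[t - tau, m]`` for tau = -lag..lag.

    Column block ``j = tau + lag`` holds all channels at lag ``tau``; frames
    outside [0, T) are zero-padded.
    """
    T, m = R.shape
    X = np.zeros((T, (2 * lag + 1) * m))
    for j, tau in enumerate(range(-lag, lag + 1)):
        if tau >= 0:
            X[tau:, j * m : (j + 1) * m] = R[: T - tau]
        else:
            X[: T + tau, j * m : (j + 1) * m] = R[-tau:]
    return X


def _normalize_pairs(R_list, S_list):
    Rs = [_as_matrix(R) for R in R_list]
    Ss = [_as_matrix(S) for S in S_list]
    if len(Rs) != len(Ss) or not Rs:
        raise ValidationError("need equal, non-empty lists of spike/spectrogram pairs")
    for i, (R, S) in enumerate(zip(Rs, Ss)):
        if R.shape[0] != S.shape[0]:
            raise ValidationError(
                f"pair {i}: {R.shape[0]} spike bins vs {S.shape[0]} spectrogram frames"
            )
    m = Rs[0].shape[1]
    F = Ss[0].shape[1]
    if any(R.shape[1] != m for R in Rs) or any(S.shape[1] != F for S in Ss):
        raise ValidationError("inconsistent channel counts across pairs")
    return Rs, Ss, m, F


def _gcv_lambda(eigvals, Q, B, SS, n_frames):
    """Pick ridge strength minimizing the generalized cross-validation score."""
    QB = Q.T @ B  # rotated cross-correlation
    qb2 = np.sum(QB**2, axis=1)
    best, best_score = _GCV_GRID[0], np.inf
    scale = np.mean(eigvals) if np.mean(eigvals) > 0 else 1.0
    for frac in _GCV_GRID:
        lam = frac * scale
        shrink = eigvals / (eigvals + lam)
        # residual sum of squares via eigen-identities
        rss = SS - np.sum(qb2 * shrink * (2.0 - shrink) / np.maximum(eigvals, 1e-300))
        df = np.sum(shrink)
        score = (rss / n_frames) / (1.0 - df / n_frames) ** 2
        if score < best_score:
            best, best_score = frac, score
    return best


def fit_decoder(
    R_list,
    S_list,
    lag: int = DEFAULT_LAG,
    ridge_lambda: float | str = DEFAULT_RIDGE,
    bin_width: float | None = None,
) -> DecoderFilter:
    """Fit the decoder on paired (binned spikegram, auditory spectrogram) lists.

    ``ridge_lambda`` is a dimensionless fraction of the mean diagonal of the
    pooled lagged autocorrelation matrix; pass 0 for the unregularized
    least-squares solution or ``"gcv"`` to select it by generalized
    cross-validation.
    """
    if lag < 0:
        raise ValidationError("lag must be >= 0")
    R_list, S_list = list(R_list), list(S_list)
    Rs, Ss, m, F = _normalize_pairs(R_list, S_list)
    if bin_width is None:
        bw = getattr(R_list[0], "bin_width", None)
        bin_width = float(bw) if bw is not None else DEFAULT_BIN_WIDTH_FALLBACK
    n_frames = sum(R.shape[0] for R in Rs)
    s_mean = sum(S.sum(axis=0) for S in Ss) / n_frames

    D = (2 * lag + 1) * m
    A = np.zeros((D, D))
    B = np.zeros((D, F))
    x_sum = np.zeros(D)
    SS = 0.0
    for R, S in zip(Rs, Ss):
        X = lagged_design(R, lag)
        A += X.T @ X
        B += X.T @ S
        x_sum += X.sum(axis=0)
        SS += float(np.sum(S**2))
    # center the pooled design columns and the stimulus
    x_mean = x_sum / n_frames
    A -= n_frames * np.outer(x_mean, x_mean)
    B -= n_frames * np.outer(x_mean, s_mean)
    SS -= n_frames * float(np.sum(s_mean**2))

    diag_scale = np.mean(np.diag(A))
    if ridge_lambda == "gcv":
        eigvals, Q = scipy.linalg.eigh(A)
        eigvals = np.maximum(eigvals, 0.0)
        ridge_lambda_value = _gcv_lambda(eigvals, Q, B, SS, n_frames)
        lam = ridge_lambda_value * max(diag_scale, 1e-300)
        W = Q @ ((Q.T @ B) / (eigvals + lam)[:, None])
        requested = "gcv"
    else:
        requested = float(ridge_lambda)
        if requested < 0:
            raise ValidationError("ridge_lambda must be >= 0")
        ridge_lambda_value = requested
        lam = requested * max(diag_scale, 1e-300)
        M = A + lam * np.eye(D)
        try:
            cond = np.linalg.cond(M)
            if not np.isfinite(cond) or cond > 1e12:
                raise np.linalg.LinAlgError(f"condition number {cond:.3g}")
            W = scipy.linalg.solve(M, B, assume_a="sym")
        except np.linalg.LinAlgError as exc:
            raise SolverError(
                f"lagged autocorrelation system is singular ({exc}); "
                "use ridge_lambda > 0"
            ) from exc

    weights = W.reshape(2 * lag + 1, m, F).transpose(2, 0, 1)
    return DecoderFilter(
        weights=weights,
        lag=lag,
        ridge_lambda=requested,
        ridge_effective=float(lam),
        bin_width=float(bin_width),
        x_mean=x_mean,
        s_mean=s_mean,
        training_metadata={
            "n_frames": int(n_frames),
            "n_utterances": len(Rs),
            "ridge_fraction": float(ridge_lambda_value),
        },
    )


DEFAULT_BIN_WIDTH_FALLBACK = 0.010


def apply_decoder(decoder: DecoderFilter, R) -> AuditorySpectrogram:
    """Reconstruct an auditory spectrogram from a binned spikegram.

    Negative predictions are retained; clipping is deferred to resynthesis.
    """
    Rm = _as_matrix(R)
    if Rm.shape[1] != decoder.n_channels:
        raise ValidationError(
            f"spikegram has {Rm.shape[1]} channels; decoder expects {decoder.n_channels}"
        )
    X = lagged_design(Rm, decoder.lag) - decoder.x_mean
    D = X.shape[1]
    W = decoder.weights.transpose(1, 2, 0).reshape(D, decoder.n_freq)
    S_hat = X @ W + decoder.s_mean
    return AuditorySpectrogram(S_hat, frame_length=decoder.bin_width)


@dataclass
class ChannelErrorProfile:
    """Per-frequency reconstruction error and power summaries."""

    e_f: np.ndarray  # sum over time of squared error, per channel
    mean_psd: np.ndarray  # time-mean of the reconstruction, per channel
    normalized_psd: np.ndarray  # mean_psd scaled to unit sum
    power_normalized_error: np.ndarray  # e_f / per-channel target power; NaN if no power


def error_profile(S, S_hat) -> ChannelErrorProfile:
    """Per-channel squared error and normalized power spectral density."""
    Sm, Hm = _as_matrix(S), _as_matrix(S_hat)
    if Sm.shape != Hm.shape:
        raise ValidationError(f"shape mismatch: {Sm.shape} vs {Hm.shape}")
    e_f = np.sum((Sm - Hm) ** 2, axis=0)
    mean_psd = Hm.mean(axis=0)
    total = mean_psd.sum()
    normalized_psd = mean_psd / total if total > 0 else np.full_like(mean_psd, 1.0 / len(mean_psd))
    power = np.sum(Sm**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pne = np.where(power > 0, e_f / np.where(power > 0, power, 1.0), np.nan)
    if np.any(power == 0):
        log.warning("%d zero-power channels: power-normalized error undefined there",
                    int(np.sum(power == 0)))
    return ChannelErrorProfile(e_f, mean_psd, normalized_psd, pne)


def train_test_split(dataset, fraction: float = 0.5, seed: int = 0):
    """Split a sequence of utterances into disjoint train/test subsets.

    The split is at the utterance level (never within an utterance),
    exhaustive, and reproducible for a given seed.
    """
    items = list(dataset)
    if len(items) < 2:
        raise ValidationError("need at least 2 utterances to split")
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_train = int(round(len(items) * fraction))
    n_train = min(max(n_train, 1), len(items) - 1)
    train = [items[i] for i in sorted(order[:n_train])]
    test = [items[i] for i in sorted(order[n_train:])]
    return train, test


def save_decoder(path, decoder: DecoderFilter) -> None:
    """Persist a fitted decoder (weights, means, metadata) to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("weights", data=decoder.weights)
        fh.create_dataset("x_mean", data=decoder.x_mean)
        fh.create_dataset("s_mean", data=decoder.s_mean)
        fh.attrs["lag"] = decoder.lag
        fh.attrs["ridge_lambda"] = str(decoder.ridge_lambda)
        fh.attrs["ridge_effective"] = decoder.ridge_effective
        fh.attrs["bin_width"] = decoder.bin_width
        for key, value in decoder.training_metadata.items():
            fh.attrs[f"meta_{key}"] = value


def load_decoder(path) -> DecoderFilter:
    """Load a decoder written by :func:`save_decoder`."""
    with h5py.File(path, "r") as fh:
        ridge = fh.attrs["ridge_lambda"]
        ridge = ridge if ridge == "gcv" else float(ridge)
        meta = {k[5:]: v for k, v in fh.attrs.items() if k.startswith("meta_")}
        return DecoderFilter(
            weights=fh["weights"][()],
            lag=int(fh.attrs["lag"]),
            ridge_lambda=ridge,
            ridge_effective=float(fh.attrs["ridge_effective"]),
            bin_width=float(fh.attrs["bin_width"]),
            x_mean=fh["x_mean"][()],
            s_mean=fh["s_mean"][()],
            training_metadata=meta,
        )
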