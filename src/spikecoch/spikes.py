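"""Stochastic spike generation and histogram binning.

A spikegram ``P`` is produced by comparing the cochleagram's per-sample firing
probabilities ``C[t, m]`` against an i.i.d. uniform random matrix ``M``:
a spike is emitted where ``C >= M``.  Averaging ``k`` independent trials gives
a smoother estimate whose expectation is ``C``.  For decoding, spikes are
accumulated into 1 ms histogram bins and then resampled to 10 ms bins.

Randomness comes from numpy's seeded PCG64 generator; the algorithm name and
seed are recorded on every artifact so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cochlea import Cochleagram
from .errors import ValidationError
from .io import EventStream

log = logging.getLogger(__name__)

RNG_ALGORITHM = "pcg64"

DEFAULT_BIN_WIDTH = 0.010  # s, decoder resolution
INTERMEDIATE_BIN = 0.001  # s, first-stage histogram resolution


@dataclass
class Spikegram:
    """Binary spike matrix (or trial average) at audio rate.

    Single-trial entries are 0/1; a ``k``-trial average lies on the grid
    {0, 1/k, ..., 1}.
    """

    values: np.ndarray  # (T, n_channels)
    k_trials: int
    bin_width: float  # s, = 1/Fs
    seed: int | None = None
    rng_algorithm: str = RNG_ALGORITHM

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class BinnedSpikegram:
    """Spike counts (possibly fractional, for trial averages) per time bin."""

    values: np.ndarray  # (n_bins, n_channels)
    bin_width: float  # s
    origin: float = 0.0  # s, left edge of bin 0
    partial_final: bool = False  # last bin does not cover a full bin width
    source_bin_width: float | None = None

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


def _check_probabilities(values: np.ndarray) -> None:
    if values.size and (np.min(values) < 0.0 or np.max(values) > 1.0):
        raise ValidationError("cochleagram values must lie in [0, 1]")


def generate_spikegram(cochleagram: Cochleagram, seed: int) -> Spikegram:
    """Draw one stochastic spikegram: spike where ``C >= M``, M ~ U[0, 1)."""
    C = np.asarray(cochleagram.values, dtype=np.float64)
    _check_probabilities(C)
    rng = np.random.default_rng(seed)
    P = (C >= rng.random(C.shape)).astype(np.float64)
    return Spikegram(P, k_trials=1, bin_width=cochleagram.bin_width, seed=seed)


def average_spikegrams(cochleagram: Cochleagram, k: int, seed: int) -> Spikegram:
    """Average ``k`` independent spikegram trials (unbiased estimate of C)."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    C = np.asarray(cochleagram.values, dtype=np.float64)
    _check_probabilities(C)
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(C)
    for _ in range(k):
        acc += C >= rng.random(C.shape)
    acc /= k
    return Spikegram(acc, k_trials=k, bin_width=cochleagram.bin_width, seed=seed)


def _bin_mass(times: np.ndarray, mass: np.ndarray, channels: np.ndarray,
              n_channels: int, bin_width: float, origin: float):
    """Histogram point masses into half-open bins [origin + i*w, origin + (i+1)*w)."""
    rel = times - origin
    idx = np.floor(rel / bin_width).astype(np.int64)
    keep = idx >= 0
    dropped = np.count_nonzero(~keep)
    if dropped:
        log.warning("%d events before the binning origin were dropped", dropped)
    idx, mass, channels = idx[keep], mass[keep], channels[keep]
    n_bins = int(idx.max()) + 1 if idx.size else 0
    out = np.zeros((n_bins, n_channels))
    np.add.at(out, (idx, channels), mass)
    return out, rel[keep]


def bin_spikes(
    source: Spikegram | EventStream,
    bin_width: float = DEFAULT_BIN_WIDTH,
    origin: float = 0.0,
    intermediate_bin: float = INTERMEDIATE_BIN,
    neuron: int | None = None,
) -> BinnedSpikegram:
    """Bin spikes into a histogram on a ``bin_width`` grid.

    Spikes are first histogrammed at ``intermediate_bin`` resolution and the
    fine bins are then summed in groups into the final bins (totals are
    identical to direct binning; the intermediate stage mirrors the 1 ms ->
    10 ms processing convention and is recorded in metadata).  A trailing
    partial bin is kept and flagged, never dropped, so total spike mass is
    conserved.  For hardware event streams the four ganglion neurons per
    channel are summed unless ``neuron`` selects a single one.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    ratio = bin_width / intermediate_bin
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        # non-integer ratio: bin directly at the requested width
        intermediate_bin = bin_width
        ratio = 1.0
    group = int(round(ratio))

    if isinstance(source, Spikegram):
        T, m = source.values.shape
        t_idx, ch_idx = np.nonzero(source.values)
        times = t_idx * source.bin_width
        mass = source.values[t_idx, ch_idx]
        n_channels = m
        total_span = T * source.bin_width - origin
        src_width = source.bin_width
    elif isinstance(source, EventStream):
        times = source.timestamp_us * 1e-6
        if neuron is not None:
            sel = source.neuron == neuron
            times = times[sel]
            ch = source.channel[sel]
        else:
            ch = source.channel
        ch_idx = ch - 1
        mass = np.ones(len(times))
        n_channels = source.n_channels
        total_span = (times.max() if len(times) else origin) - origin
        src_width = None
    else:
        raise ValidationError(f"cannot bin object of type {type(source).__name__}")

    fine, _ = _bin_mass(np.asarray(times, dtype=np.float64), np.asarray(mass, dtype=np.float64),
                        np.asarray(ch_idx), n_channels, intermediate_bin, origin)
    n_fine = fine.shape[0]
    if n_fine == 0:
        return BinnedSpikegram(np.zeros((0, n_channels)), bin_width, origin, False, src_width)
    n_coarse = int(np.ceil(n_fine / group))
    pad = n_coarse * group - n_fine
    if pad:
        fine = np.vstack([fine, np.zeros((pad, n_channels))])
    coarse = fine.reshape(n_coarse, group, n_channels).sum(axis=1)
    partial = total_span > 0 and (total_span / bin_width) % 1.0 > 1e-9
    return BinnedSpikegram(coarse, bin_width, origin, bool(partial), src_width)
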