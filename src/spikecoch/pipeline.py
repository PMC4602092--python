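"""End-to-end orchestration: audio -> spikes -> decoder -> reconstructed audio.

These helpers chain the individual stages for whole-dataset experiments such
as the noise-robustness protocol: mix each utterance with babble at a target
SNR, encode the (noisy) audio to binned spikegrams, fit the decoder on the
training split against the CLEAN auditory spectrograms, decode every
utterance, and invert the decoded spectrograms back to waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audspec import AuditorySpectrogram, audspec
from .cochlea import FilterbankDesign, cochleagram, design_filterbank
from .evaluation import mix_at_snr
from .io import AudioSignal
from .reconstruction import DecoderFilter, apply_decoder, fit_decoder, train_test_split
from .resynthesis import invert_spectrogram
from .spikes import average_spikegrams, bin_spikes, generate_spikegram


def encode_to_binned(
    audio: AudioSignal,
    k_trials: int = 10,
    seed: int = 0,
    design: FilterbankDesign | None = None,
    bin_width: float = 0.010,
):
    """Audio -> cochleagram -> (averaged) spikegram -> binned spikegram."""
    if design is None:
        design = design_filterbank(sample_rate=audio.sample_rate)
    coch = cochleagram(audio, design)
    if k_trials == 1:
        spk = generate_spikegram(coch, seed)
    else:
        spk = average_spikegrams(coch, k_trials, seed)
    return bin_spikes(spk, bin_width=bin_width)


def _align(R, S):
    """Trim a spike histogram and spectrogram to a common frame count."""
    n = min(R.values.shape[0], S.values.shape[0])
    R.values = R.values[:n]
    S.values = S.values[:n]
    return R, S


@dataclass
class ReconstructionRun:
    """Everything produced by one dataset-level reconstruction experiment."""

    inputs: list  # AudioSignal actually encoded (noisy if snr_db was set)
    targets: list  # clean auditory spectrograms
    binned: list
    decoded: list  # decoder outputs, aligned with inputs
    reconstructed: list  # inverted waveforms (AudioSignal, 16 kHz)
    decoder: DecoderFilter
    train_idx: list
    test_idx: list
    snr_db: float | None = None


def run_reconstruction(
    signals,
    seed: int = 0,
    k_trials: int = 10,
    lag: int = 15,
    ridge_lambda: float | str = 1e-3,
    snr_db: float | None = None,
    noise: AudioSignal | None = None,
    invert_iters: int = 60,
    fraction: float = 0.5,
    design: FilterbankDesign | None = None,
) -> ReconstructionRun:
    """Run the full encode/fit/decode/invert pipeline over a dataset.

    When ``snr_db`` is given, each signal is mixed with ``noise`` (babble)
    before encoding while the decoding targets stay the CLEAN spectrograms, so
    the fitted mapping learns to suppress the masker.  The decoder is fitted
    on the utterance-level training split only and applied to every utterance.
    """
    signals = list(signals)
    rng = np.random.default_rng(seed)
    if snr_db is not None:
        if noise is None:
            raise ValueError("snr_db given but no noise signal provided")
        inputs = [
            mix_at_snr(s, noise, snr_db, seed=int(rng.integers(0, 2**31 - 1)))
            for s in signals
        ]
    else:
        inputs = signals

    if design is None:
        design = design_filterbank(sample_rate=inputs[0].sample_rate)
    targets = [audspec(s) for s in signals]
    binned = [
        encode_to_binned(x, k_trials=k_trials, seed=int(rng.integers(0, 2**31 - 1)),
                         design=design)
        for x in inputs
    ]
    pairs = [_align(R, S) for R, S in zip(binned, targets)]
    train_idx, test_idx = train_test_split(range(len(signals)), fraction=fraction, seed=seed)
    decoder = fit_decoder(
        [pairs[i][0] for i in train_idx],
        [pairs[i][1] for i in train_idx],
        lag=lag,
        ridge_lambda=ridge_lambda,
    )
    decoded = [apply_decoder(decoder, R) for R, _ in pairs]
    reconstructed = [
        invert_spectrogram(S_hat, max_iter=invert_iters,
                           seed=int(rng.integers(0, 2**31 - 1))).audio
        for S_hat in decoded
    ]
    return ReconstructionRun(
        inputs=inputs,
        targets=[S for _, S in pairs],
        binned=[R for R, _ in pairs],
        decoded=decoded,
        reconstructed=reconstructed,
        decoder=decoder,
        train_idx=list(train_idx),
        test_idx=list(test_idx),
        snr_db=snr_db,
    )
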