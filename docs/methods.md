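# Methods

`spikecoch` models the round trip **audio → spikes → audio** through a
spiking cochlea: a Lyon-style cascade front end converts sound to per-channel
firing probabilities, Bernoulli sampling produces spike trains, a lagged
linear decoder maps 10 ms spike histograms back to an auditory spectrogram,
and iterative convex projection inverts the spectrogram to a waveform.  The
fidelity of the spike code is then measured with intelligibility metrics and
a word-classification protocol.  This note records the model, the defaults,
and the numerical choices, including the places where the design was
genuinely open.

## Cochlear front end

The cascade consists of 64 second-order sections.  Channel bandwidth follows
`B(f) = sqrt(f^2 + Eb^2) / Q_ear` with ear break frequency `Eb = 1000 Hz` and
ear quality factor `Q_ear = 8` (default).  Channel spacing is uniform on the
warped axis `a(f) = ln(f + sqrt(f^2 + Eb^2))`, on which one step corresponds
to `step_factor` (default 0.25) bandwidths.  The top frequency is Nyquist
minus one zero-offset of headroom; the bottom frequency is where the pole
quality factor reaches 0.5, i.e. `Eb / sqrt(4 Q_ear^2 - 1) ≈ 62.6 Hz`.  With
the literal per-step recurrence these constants produce ~93 stages over that
span at 20 kHz; since the front end is specified as 64 channels covering that
same range, we place the requested number of stages uniformly on the warped
axis between the same endpoints.  The default 64-stage design at 20 kHz then
spans ≈63 Hz to ≈9.8 kHz.  Exact coefficient parity with any toolbox is not a
goal; the contracts are the frequency span, per-stage stability (poles
strictly inside the unit circle, checked at design time) and tonotopy
(verified against the cascade's analytic frequency response).

Each stage is a biquad with a resonant pole pair at the channel frequency
(`Q = f/B(f)`, saturating at `Q_ear` for high channels) and a zero pair 1.5
step-bandwidths above it (`Q = 5`), normalized to unity DC gain.  The tap
after each stage is half-wave rectified (inner-hair-cell model).  Automatic
gain control is deliberately not modeled; quiet passages therefore produce
few spikes.

**Probability normalization.**  The rectified analog outputs serve as
per-sample firing probabilities, but the mapping to [0, 1] is not fixed by
the model.  We scale each recording by a single global gain such that the
99.9th percentile of the rectified values maps to `p_max = 0.5`, then clip to
[0, 1].  Rationale: at a 20 kHz audio rate, per-bin Bernoulli probabilities
must stay well below 1 or the spike code saturates; 0.5 at the 99.9th
percentile keeps the loudest samples sub-saturating while preserving dynamic
range.  The gain is stored on the cochleagram so the mapping is invertible
and reportable.  This is a known divergence risk when comparing against any
toolbox's raw analog outputs.

## Spike generation and binning

A spike is emitted in bin `(t, m)` when `C[t, m] >= M[t, m]` with `M` i.i.d.
uniform on [0, 1); the printed `>=` resolves the probability-zero tie.  The
bin width is one audio sample (`0.05 ms` at 20 kHz).  Trial averaging over
`k ∈ {1, 10, 100}` trials gives an unbiased estimate of `C` with variance
`C(1-C)/k`.  Averaging is performed at audio rate and binned afterwards; the
order is mathematically irrelevant for sums but is recorded here.  Binning
uses half-open bins `[origin + i·w, origin + (i+1)·w)` at 1 ms resolution,
then sums groups of ten into 10 ms decoder bins; a trailing partial bin is
kept and flagged rather than dropped so spike mass is conserved.  For
hardware event streams the four ganglion neurons per channel are summed into
one channel count by default (a single neuron can be selected); the
combination rule is not fixed by the hardware description, so this is a
recorded design choice.  All randomness flows through numpy's seeded PCG64
generator, and seeds are recorded in artifact metadata.

## Auditory spectrogram

The decoding target is a 128-channel, 10 ms-frame time-frequency
representation.  Channels sit on a geometric grid from 180 Hz to 7246 Hz
(`f(k) = 180 · r^k`, `r = (7246/180)^(1/128) ≈ 1.0293`; channel 10 ≈ 240 Hz,
channel 40 ≈ 571 Hz, channel 60 ≈ 1017.5 Hz).  One caption-level source
prints 7240 Hz for the upper edge; we default to 7246 Hz and leave it
configurable.  Audio is polyphase-resampled to 16 kHz, filtered with
constant-Q order-2 Butterworth bandpasses whose −3 dB edges meet at the
geometric midpoints, half-wave rectified, leaky-integrated (first-order,
τ = 10 ms), and sampled at the final sample of each 10 ms frame.  The exact
cochlear-filter coefficients of the reference auditory-model toolbox are not
published, so the channels are implemented as constant-Q bandpasses on the
documented grid; the grid, tonotopy and frame timing are the contracts the
decoder and metrics consume.  Amplitude compression (cube-root or log) is off
by default and available as a flag.

## Linear decoder (optimal stimulus prior)

The decoder estimates `S_f(t) ≈ Σ_m Σ_{τ=-L}^{L} g_f(τ, m) R(t-τ, m)` with
`L = 15` bins (150 ms of context on each side) by normalized reverse
correlation, independently per output channel: the pooled lagged
autocorrelation of the spike histograms normalizes the spike-stimulus
cross-correlation.  `g` is time-invariant.  Choices that the formulation
leaves open:

* **Regularization.**  Ridge on the autocorrelation, with strength expressed
  as a fraction of the mean autocorrelation diagonal (default `1e-3` so the
  behaviour is scale-free); a generalized-cross-validation selector
  (`ridge_lambda="gcv"`, 17-point log grid from 1e-7 to 10) is available and
  is what the dataset-level pipeline uses.  The effective value is stored in
  the decoder metadata.
* **Boundaries.**  Lag windows are zero-padded at utterance edges; utterances
  are never concatenated across their boundary when accumulating
  correlations.
* **Centering.**  Each lagged regressor is centered by its own pooled mean
  (equal to the channel mean up to edge effects) and the stimulus mean is
  restored on application.  Centering the design columns rather than the raw
  channels keeps the fit exactly linear-consistent with zero padding: on a
  noiseless lagged-linear fixture the fit recovers the generating filter to
  machine precision, which per-channel pre-centering would break at the
  edges.
* **Degeneracy.**  With `ridge_lambda = 0` a condition number above 1e12
  raises a solver error that suggests ridge, rather than returning garbage.

Error profiles report, per output channel, the summed squared error, the
time-mean reconstructed power, its unit-sum normalization, and the error
normalized by per-channel target power (flagged undefined for silent
channels).

## Spectrogram inversion

Inversion starts from Gaussian white noise and alternates between the signal
domain and the spectrogram constraint: analyze the current signal with the
same filterbank/rectifier/integrator chain, rescale each subband by the ratio
of target to current envelope, and project the rescaled subbands back through
the **adjoint** (time-reversed) filterbank before summing.  The adjoint step
matters: the 128 bands overlap so heavily that naive re-summation lets
differently phased neighbouring subbands cancel, and the iteration stalls at
a high distance; with the adjoint the per-channel round trip is zero-phase
and the distance decreases monotonically in practice.  Ratios are clipped to
[0.1, 10] per iteration (so near-silent subbands cannot explode) and
linearly interpolated between frame centers before being applied at audio
rate.  Defaults: 200 iterations maximum, stop when the relative improvement
falls below 1e-4; neither constant is fixed by the model, both are
configurable, and the distance trace is returned for inspection.  The
returned waveform is the best iterate on the target's amplitude scale; peak
normalization to 0.9 happens only when writing a WAV for listening, because
the analysis chain is homogeneous and rescaling would break the reported
distance.  Typical self-consistency on targets that are themselves analysis
outputs is a relative distance of 0.15-0.2; exact inversion is impossible
because rectification discards sign and phase.

## Evaluation

**STOI.**  Implemented as published: resample to 10 kHz, drop frames more
than 40 dB below the loudest clean frame, 512-point STFT of 256-sample Hann
frames at 50% overlap, 15 one-third-octave bands from 150 Hz, and clipped
(−15 dB bound), normalized envelope correlation over 30-frame (~386 ms)
segments.  The test suite cross-checks it against a second, deliberately
loop-based transcription of the same published procedure that shares no code
with the implementation.  PESQ is an ITU-standardized metric and is not
re-implemented; an optional hook calls an external binary when present.

**Classifier.**  The word recognizer is a deterministic segmental template
model over 39-dimensional MFCC features (13 cepstra from 26 mel bands,
25 ms/10 ms framing, pre-emphasis 0.97, plus deltas and accelerations with a
±2-frame regression window): each class is summarized by 5 equal-duration
temporal segments, each a diagonal-covariance Gaussian over globally
standardized frames, and classification is the maximum summed log-likelihood.
This replaces a Baum-Welch-trained 16-mixture HMM toolchain deliberately: the
protocol needs a reproducible, dependency-free classifier to compare
train/test domain combinations, not state-of-the-art accuracy, and absolute
accuracies from the original corpus-plus-HMM setup are out of scope.  The
matched/mismatched protocol reuses one stratified utterance-level split
(seeded) across all grid conditions so accuracies are comparable.

**Noise robustness.**  Babble is the normalized sum of eight independent
synthetic talkers.  Mixtures realize the requested SNR exactly over the
signal support.  For each SNR condition the decoder is retrained on
noisy-audio spikes against **clean** spectrogram targets — the spike
threshold suppresses the noise floor, so the retrained decoder acts as a
denoiser — and audio is resynthesized from the decoded spectrograms.  The
package asserts the qualitative claims (matched-statistics training beats
mismatched; reconstructed audio overtakes noisy originals at or below −5 dB;
decoded spectrograms carry less silent-frame energy than noisy ones at
−10 dB) as ordering relations, not as absolute percentages.

## Synthetic data

Tokens are formant-modulated harmonic sounds: a jittered glottal impulse
train (1% period jitter plus a small aspiration floor) drives two or three
time-varying second-order formant resonators under an attack/sustain/release
envelope.  Classes are (F1, F2) targets on a 4×4 grid between roughly
(320-770) × (1050-2250) Hz — separable by construction, verified by a
nearest-centroid oracle in parameter space — with per-exemplar jitter of
±10% on the fundamental and ±5% on formant centers to emulate speaker
variability.  `linear_pair_fixture` generates decoder oracles: i.i.d. Poisson
counts (10 ms bins aggregate many near-Bernoulli draws, so counts are the
right semantics) mapped through a known random lagged filter, plus Gaussian
noise at a chosen SNR.

What the generator does **not** emulate: consonant transients, coarticulation,
speaker-level spectral tilt, room acoustics, and broadband onsets.  One
consequence shows up directly in the numbers: because exemplars jitter the
fundamental by ±10% and the spectrogram channels are only 2.9% apart, the
harmonic comb of an unseen token is not predictable from the spike code, so
held-out decoded-spectrogram correlations plateau around 0.4-0.8 at fixture
scale even though training correlations exceed 0.9.  Passing tests therefore
demonstrate the machinery and the ordering trends, not natural-speech
reconstruction quality.

## Problem sizes and runtime

The test and acceptance workloads are sized for a single CPU: the
noise-robustness protocol uses 4 classes × 6 exemplars of 0.45 s tokens,
10-trial spikegrams, decoder lag 3 with GCV ridge, 35 inversion iterations,
and a clean + {0, −5, −10} dB condition grid (~2 minutes); decoder-oracle
checks use T ≤ 200, and parameter recovery uses T = 5000 frames.  All
experiment entry points take explicit seeds and are deterministic given them.

## Known limitations

* The cochlea front end has no AGC, outer/middle-ear pre-emphasis, or
  binaural stage; hardware circuit behaviour (transistor mismatch, the four
  threshold-split ganglion neurons) is represented only through the AER event
  format.
* The decoder is linear and time-invariant by design; it lower-bounds, not
  measures, the information in the spike code.
* The probability normalization makes cochleagrams recording-relative;
  comparing absolute spike rates across recordings requires the stored gain.
* STOI is validated against an internal reference transcription, not against
  an external implementation, since none is available in this environment.
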