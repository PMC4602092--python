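"""Independent, loop-based reference implementation of the STOI measure.

Used only as a cross-check oracle in tests.  It is a direct, deliberately
unvectorized transcription of the published short-time objective
intelligibility procedure (10 kHz rate, silent-frame removal at 40 dB dynamic
range, 512-point STFT of 256-sample Hann frames with 50% overlap, 15
one-third-octave bands from 150 Hz, 30-frame segments, -15 dB clipped and
normalized envelope correlation) and shares no code with the package's
implementation.
"""

import numpy as np
from scipy.fft import fft
from scipy.signal import resample_poly


def _thirds(fs=10000.0, nfft=512, n_bands=15, mn=150.0):
    freqs = np.array([i * fs / nfft for i in range(nfft // 2 + 1)])
    bands = []
    for k in range(n_bands):
        lo = mn * 2.0 ** ((2 * k - 1) / 6.0)
        hi = mn * 2.0 ** ((2 * k + 1) / 6.0)
        bands.append([i for i, f in enumerate(freqs) if lo <= f < hi])
    return bands


def reference_stoi(clean, degraded, fs):
    """STOI score computed with explicit loops; oracle for tests only."""
    if fs != 10000:
        from fractions import Fraction

        frac = Fraction(10000 / fs).limit_denominator(1000)
        clean = resample_poly(clean, frac.numerator, frac.denominator)
        degraded = resample_poly(degraded, frac.numerator, frac.denominator)
    N, hop = 256, 128
    w = np.hanning(N + 2)[1:-1]

    # silent-frame removal based on the clean signal
    n_frames = (len(clean) - N) // hop + 1
    kept = []
    energies = []
    for i in range(n_frames):
        seg = clean[i * hop : i * hop + N] * w
        energies.append(20 * np.log10(np.sqrt(np.sum(seg**2)) + 1e-300))
    emax = max(energies)
    for i in range(n_frames):
        if energies[i] > emax - 40.0:
            kept.append(i)
    xs = np.zeros((len(kept) - 1) * hop + N if kept else 0)
    ys = np.zeros_like(xs)
    for j, i in enumerate(kept):
        xs[j * hop : j * hop + N] += clean[i * hop : i * hop + N] * w
        ys[j * hop : j * hop + N] += degraded[i * hop : i * hop + N] * w

    bands = _thirds()
    n_frames = (len(xs) - N) // hop + 1
    X = np.zeros((15, n_frames))
    Y = np.zeros((15, n_frames))
    for i in range(n_frames):
        fx = fft(xs[i * hop : i * hop + N] * w, 512)
        fy = fft(ys[i * hop : i * hop + N] * w, 512)
        for j, members in enumerate(bands):
            X[j, i] = np.sqrt(sum(abs(fx[k]) ** 2 for k in members))
            Y[j, i] = np.sqrt(sum(abs(fy[k]) ** 2 for k in members))

    seg_len = 30
    c = 10.0 ** (15.0 / 20.0)
    d_values = []
    for m in range(seg_len, n_frames + 1):
        for j in range(15):
            x = X[j, m - seg_len : m]
            y = Y[j, m - seg_len : m]
            alpha = np.sqrt(np.sum(x**2) / (np.sum(y**2) + 1e-300))
            yp = np.array([min(alpha * yv, xv * (1 + c)) for xv, yv in zip(x, y)])
            xm, ym = x - x.mean(), yp - yp.mean()
            denom = np.sqrt(np.sum(xm**2)) * np.sqrt(np.sum(ym**2)) + 1e-300
            d_values.append(np.sum(xm * ym) / denom)
    return float(np.mean(d_values))
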