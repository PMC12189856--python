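"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the library code paths they check: the band-power
oracle uses a raw one-sided periodogram instead of Welch averaging, the
ApEn oracle counts templates with explicit Python loops, and the DWT oracle
runs the filter bank by explicit symmetric extension and convolution.
"""

import numpy as np
import pywt


def periodogram_band_power(x, fs, low, high):
    """Mean PSD over [low, high) from a direct one-sided periodogram."""
    n = len(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = np.abs(np.fft.rfft(x)) ** 2 / (fs * n)
    psd[1:-1] *= 2
    mask = (freqs >= low) & (freqs < high)
    return psd[mask].mean()


def apen_bruteforce(x, m, r):
    """Approximate entropy by direct template counting (O(n^2) loops),
    Chebyshev distance, self-matches included."""
    x = np.asarray(x, float)
    n = len(x)
    tol = r * x.std()

    def phi(mm):
        templates = [x[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for ti in templates:
            count = sum(1 for tj in templates if np.max(np.abs(ti - tj)) <= tol)
            total += np.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def dwt_oracle(x, wavelet_name):
    """One DWT analysis step by explicit half-sample-symmetric extension and
    full convolution with the decomposition filters (pywt 'symmetric')."""
    w = pywt.Wavelet(wavelet_name)
    flen = w.dec_len
    ext = np.concatenate([x[: flen - 1][::-1], x, x[::-1][: flen - 1]])
    out_len = (len(x) + flen - 1) // 2
    a = np.convolve(ext, w.dec_lo)[flen::2][:out_len]
    d = np.convolve(ext, w.dec_hi)[flen::2][:out_len]
    return a, d
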