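"""Independent brute-force oracles used to check the library's numerics.

Everything here is deliberately written the slow, obvious way (explicit
loops, direct formula evaluation) and never calls back into the package's
own computational paths.
"""

import math

import numpy as np


def percentile_linear(samples, p):
    """Linear-interpolation percentile via explicit order statistics."""
    x = sorted(float(v) for v in samples)
    n = len(x)
    h = (n - 1) * p / 100.0
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    return x[lo] + (h - lo) * (x[hi] - x[lo])


def clamp_norm(x, q10, q90):
    return min(1.0, max(0.0, (x - q10) / (q90 - q10)))


def biquad_cascade_filtfilt(sos, x):
    """Zero-phase filtering: forward and reverse passes of an explicit
    direct-form-II-transposed biquad cascade with zero initial state."""

    def one_pass(sig):
        y = np.array(sig, dtype=float)
        for b0, b1, b2, a0, a1, a2 in sos:
            z1 = z2 = 0.0
            out = np.empty_like(y)
            for i, xi in enumerate(y):
                yi = b0 * xi + z1
                z1 = b1 * xi - a1 * yi + z2
                z2 = b2 * xi - a2 * yi
                out[i] = yi
            y = out
        return y

    return one_pass(one_pass(x)[::-1])[::-1]


def analytic_envelope_sq(x):
    """Squared magnitude of the analytic signal via an explicit FFT mask."""
    n = len(x)
    X = np.fft.fft(x)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    return np.abs(np.fft.ifft(X * h)) ** 2


def moving_average_same(x, win):
    """'same'-mode moving average by explicit window sums."""
    n = len(x)
    out = np.zeros(n)
    # replicate np.convolve's 'same' centring: output i is full-convolution
    # index i + (win-1)//2, i.e. the sum over x[i+(win-1)//2-win+1 .. i+(win-1)//2]
    for i in range(n):
        lo = i + (win - 1) // 2 - win + 1
        acc = 0.0
        for j in range(win):
            k = lo + j
            if 0 <= k < n:
                acc += x[k]
        out[i] = acc / win
    return out


def welch_msc(x, y, fs, nperseg):
    """Magnitude-squared coherence: Hann window, 50% overlap, constant detrend.

    Direct DFT cross-spectrum accumulation, no library spectral calls.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    step = nperseg - nperseg // 2  # hop with 50% overlap (noverlap = nperseg//2)
    k = np.arange(nperseg)
    window = 0.5 - 0.5 * np.cos(2 * np.pi * k / nperseg)  # periodic Hann
    starts = range(0, len(x) - nperseg + 1, step)
    pxx = pyy = pxy = None
    n_seg = 0
    for s in starts:
        xs = x[s : s + nperseg]
        ys = y[s : s + nperseg]
        xs = (xs - xs.mean()) * window
        ys = (ys - ys.mean()) * window
        X = np.fft.rfft(xs)
        Y = np.fft.rfft(ys)
        if pxx is None:
            pxx = np.abs(X) ** 2
            pyy = np.abs(Y) ** 2
            pxy = np.conj(X) * Y
        else:
            pxx += np.abs(X) ** 2
            pyy += np.abs(Y) ** 2
            pxy += np.conj(X) * Y
        n_seg += 1
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    msc = np.abs(pxy) ** 2 / (pxx * pyy)
    return freqs, msc, n_seg


def scan_recovery(values, times, onset, threshold, dwell_n, max_window):
    """Exhaustive-scan recovery detector: for every candidate start sample in
    the search window, literally check each of the next dwell_n samples."""
    in_window = [
        i for i, t in enumerate(times) if onset - 1e-9 <= t < onset + max_window - 1e-9
    ]
    if not in_window:
        return max_window, True
    lo, hi = in_window[0], in_window[-1] + 1
    for start in range(lo, hi):
        if start + dwell_n > hi:
            break
        ok = True
        for j in range(start, start + dwell_n):
            if not values[j] < threshold:
                ok = False
                break
        if ok:
            return max(0.0, times[start] - onset), False
    return max_window, True


def spectral_entropy_bits(image):
    """Shannon entropy of the DC-excluded normalized 2-D power spectrum."""
    spec = np.abs(np.fft.fft2(np.asarray(image, dtype=float))) ** 2
    flat = list(spec.ravel())
    flat[0] = 0.0
    total = sum(flat)
    if total <= 0:
        return 0.0
    h = 0.0
    for v in flat:
        if v > 0:
            p = v / total
            h -= p * math.log2(p)
    return h
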