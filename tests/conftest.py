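import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_welch_msc(x, y, fs, nperseg, noverlap):
    """Independent Welch magnitude-squared coherence (direct FFT loop)."""
    step = nperseg - noverlap
    # periodic hann, as used by Welch-style estimators
    win = 0.5 * (1 - np.cos(2 * np.pi * np.arange(nperseg) / nperseg))
    sxx = syy = sxy = 0.0
    k = 0
    for start in range(0, len(x) - nperseg + 1, step):
        xs = x[start : start + nperseg]
        ys = y[start : start + nperseg]
        fx = np.fft.rfft((xs - xs.mean()) * win)
        fy = np.fft.rfft((ys - ys.mean()) * win)
        sxx = sxx + np.abs(fx) ** 2
        syy = syy + np.abs(fy) ** 2
        sxy = sxy + fx * np.conj(fy)
        k += 1
    freqs = np.fft.rfftfreq(nperseg, 1 / fs)
    msc = np.abs(sxy) ** 2 / (sxx * syy)
    return freqs, msc, k
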