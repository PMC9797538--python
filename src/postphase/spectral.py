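"""Shared Welch power-spectral-density machinery.

Both the EEG band powers and the EMG frequency-domain features go through
this module so they share one PSD convention: Hann windows of 2 s, 50 %
overlap, one-sided density normalization (power = integral of PSD over
frequency, which matches time-domain variance for zero-mean signals).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

WELCH_WINDOW_S = 2.0
WELCH_OVERLAP = 0.5


def welch_psd(x: np.ndarray, fs: float,
              window_s: float = WELCH_WINDOW_S) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD along the last axis. Returns (freqs, psd)."""
    n = x.shape[-1]
    nperseg = min(int(round(window_s * fs)), n)
    return signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                        noverlap=int(nperseg * WELCH_OVERLAP), axis=-1)


def band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Integral of the PSD over [lo, hi), rectangle rule on the Welch grid."""
    df = freqs[1] - freqs[0]
    mask = (freqs >= lo) & (freqs < hi)
    return psd[..., mask].sum(axis=-1) * df


def total_power(freqs: np.ndarray, psd: np.ndarray) -> np.ndarray:
    df = freqs[1] - freqs[0]
    return psd.sum(axis=-1) * df


def mean_frequency(freqs: np.ndarray, psd: np.ndarray) -> float:
    """Spectral centroid MNF = Σ f·P / Σ P."""
    p = psd.sum()
    return float((freqs * psd).sum() / p) if p > 0 else 0.0


def median_frequency(freqs: np.ndarray, psd: np.ndarray) -> float:
    """Frequency splitting the power mass in half (linear interpolation)."""
    c = np.cumsum(psd)
    if c[-1] <= 0:
        return 0.0
    return float(np.interp(0.5 * c[-1], c, freqs))


def spectral_edge(freqs: np.ndarray, psd: np.ndarray, fraction: float = 0.95) -> float:
    """Frequency below which *fraction* of the total power lies."""
    c = np.cumsum(psd)
    if c[-1] <= 0:
        return 0.0
    return float(np.interp(fraction * c[-1], c, freqs))


def peak_frequency(freqs: np.ndarray, psd: np.ndarray) -> float:
    return float(freqs[int(np.argmax(psd))])


def spectral_moment(freqs: np.ndarray, psd: np.ndarray, order: int) -> float:
    df = freqs[1] - freqs[0]
    return float(((freqs ** order) * psd).sum() * df)


def spectral_entropy(psd: np.ndarray) -> float:
    """Shannon entropy (bits) of the PSD normalized to a distribution."""
    p = psd[psd > 0]
    s = p.sum()
    if s <= 0:
        return 0.0
    q = p / s
    return float(-(q * np.log2(q)).sum())
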