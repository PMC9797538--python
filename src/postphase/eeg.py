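"""EEG band-power features: 5 bands × 5 cortical lobes = 25 per phase.

The per-phase pipeline is: zero-phase band-pass 1–45 Hz + 50 Hz notch
(after resampling to 1,024 Hz if needed), Welch PSD per channel, relative
power in the five canonical bands (delta 1–4, theta 4–8, alpha 8–13, beta
13–30, low gamma 30–45 Hz) with the total 1–45 Hz power as denominator so
each channel's five relative powers sum to one, then the arithmetic mean
over the channels of each lobe.

Feature names follow ``EEG__<lobe>__<band>``.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction

import numpy as np
from scipy import signal

from .montage import DEFAULT_LOBE_MAP, LOBES
from .segmentation import PhaseSegment
from .spectral import band_power, welch_psd

FS_TARGET = 1024.0
BAND_EDGE_LO = 1.0
BAND_EDGE_HI = 45.0
NOTCH_HZ = 50.0


@dataclasses.dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo {self.lo} must be < hi {self.hi}")


DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("low_gamma", 30.0, 45.0),
)


def preprocess_eeg(segment: PhaseSegment, fs_target: float = FS_TARGET) -> PhaseSegment:
    """Resample to ``fs_target`` and apply zero-phase 1–45 Hz band-pass + 50 Hz notch."""
    if fs_target <= 2 * BAND_EDGE_HI:
        raise ValueError(
            f"fs_target {fs_target} Hz must exceed twice the 45 Hz band edge"
        )
    data, fs = segment.data, segment.fs
    if fs != fs_target:
        frac = Fraction(fs_target / fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
        fs = fs_target
    sos = signal.butter(4, [BAND_EDGE_LO, BAND_EDGE_HI], btype="bandpass",
                        fs=fs, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=1)
    b, a = signal.iirnotch(NOTCH_HZ, Q=30.0, fs=fs)
    data = signal.filtfilt(b, a, data, axis=1)
    w0, _ = segment.window
    return PhaseSegment(
        label=segment.label, modality=segment.modality, data=data, fs=fs,
        window=(w0, w0 + data.shape[1] / fs), channel_names=segment.channel_names,
    )


def relative_band_power(segment: PhaseSegment,
                        bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> np.ndarray:
    """Per-channel relative band powers (n_channels × n_bands, rows sum to 1)."""
    zero = np.all(segment.data == 0.0, axis=1)
    if zero.any():
        bad = [segment.channel_names[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero channel(s) {bad}: relative power undefined")
    freqs, psd = welch_psd(segment.data, segment.fs)
    powers = np.stack([band_power(freqs, psd, b.lo, b.hi) for b in bands], axis=1)
    total = band_power(freqs, psd, BAND_EDGE_LO, BAND_EDGE_HI)
    if np.any(total <= 0):
        bad = [segment.channel_names[i] for i in np.flatnonzero(total <= 0)]
        raise ValueError(f"channel(s) {bad} have no in-band power")
    return powers / total[:, None]


def lobe_average(channel_powers: np.ndarray,
                 channel_names: tuple[str, ...],
                 lobe_map: dict[str, str] | None = None,
                 bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> dict[str, float]:
    """Mean relative band power over each lobe's channels → 25 named features."""
    lobe_map = lobe_map or DEFAULT_LOBE_MAP
    missing = [c for c in lobe_map if c not in channel_names]
    if missing:
        raise ValueError(f"lobe map channels absent from segment: {missing}")
    idx = {c: i for i, c in enumerate(channel_names)}
    out: dict[str, float] = {}
    for lobe in LOBES:
        rows = [idx[c] for c, l in lobe_map.items() if l == lobe]
        if not rows:
            raise ValueError(f"lobe {lobe!r} has no channels")
        mean = channel_powers[rows].mean(axis=0)
        for band, v in zip(bands, mean):
            out[f"EEG__{lobe}__{band.name}"] = float(v)
    return out


def eeg_phase_features(segment: PhaseSegment,
                       bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                       lobe_map: dict[str, str] | None = None,
                       preprocess: bool = True) -> dict[str, float]:
    """Full 25-feature EEG vector for one phase segment."""
    if preprocess:
        segment = preprocess_eeg(segment, segment.fs if segment.fs == FS_TARGET
                                 else FS_TARGET)
    powers = relative_band_power(segment, bands)
    return lobe_average(powers, segment.channel_names, lobe_map, bands)
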