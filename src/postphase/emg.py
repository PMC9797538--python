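"""Surface-EMG conditioning and the 43-feature battery per channel.

Conditioning is a zero-phase 4th-order Butterworth band-pass, 15–500 Hz,
at 1,600 Hz.  The battery covers the canonical time-domain set (MAV, RMS,
waveform length, DASDV/LDASDV, zero crossings, slope-sign changes, Willison
amplitude, log detector, Hjorth parameters, higher moments, ...), the
Teager–Kaiser energy operator summaries (TKEO mean, LTKEO) and the maximum
fractal length (MFL), plus Welch-PSD frequency-domain descriptors (mean /
median / peak frequency, spectral moments, spectral entropy, band-power
fractions).  Exactly 43 operators per channel; over the six channels
(TA/GL/SOL × L/R) that is 258 features per phase, named
``EMG__<muscle>_<side>__<feature>``.

Every logarithm is guarded by ``EPS = 1e-12`` so constant segments yield
finite (degenerate) values instead of crashing batch extraction.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .segmentation import PhaseSegment
from .spectral import (band_power, mean_frequency, median_frequency,
                       peak_frequency, spectral_edge, spectral_entropy,
                       spectral_moment, total_power, welch_psd)

EPS = 1e-12
BAND_LO = 15.0
BAND_HI = 500.0
FS_EMG = 1600.0
#: Willison-amplitude / myopulse threshold, mV (conventional ~20 µV level).
WAMP_THRESHOLD = 0.02
#: Low/high band split for frequency-ratio features, Hz.
FREQ_SPLIT = 100.0


def bandpass_emg(segment: PhaseSegment) -> PhaseSegment:
    """Zero-phase 4th-order Butterworth band-pass, 15–500 Hz."""
    if segment.fs <= 1000.0:
        raise ValueError(
            f"fs {segment.fs} Hz too low for a 500 Hz cutoff (needs > 1,000 Hz)"
        )
    sos = signal.butter(4, [BAND_LO, BAND_HI], btype="bandpass",
                        fs=segment.fs, output="sos")
    data = signal.sosfiltfilt(sos, segment.data, axis=1)
    return PhaseSegment(label=segment.label, modality=segment.modality,
                        data=data, fs=segment.fs, window=segment.window,
                        channel_names=segment.channel_names)


# -- core operators ---------------------------------------------------------

def tkeo(x: np.ndarray) -> np.ndarray:
    """Teager–Kaiser energy Ψ[x](n) = x(n)² − x(n−1)·x(n+1); length N−2."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("tkeo requires at least 3 samples")
    return x[1:-1] ** 2 - x[:-2] * x[2:]


def ltkeo(x: np.ndarray) -> float:
    """Natural log of (mean |Ψ| + EPS)."""
    return float(np.log(np.mean(np.abs(tkeo(x))) + EPS))


def dasdv_ldasdv(x: np.ndarray) -> tuple[float, float]:
    """DASDV = sqrt(mean of squared successive differences, N−1 norm) and its log."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("dasdv requires at least 2 samples")
    d = np.diff(x)
    dasdv = float(np.sqrt((d ** 2).sum() / (x.size - 1)))
    return dasdv, float(np.log(dasdv + EPS))


def mfl(x: np.ndarray) -> float:
    """Maximum fractal length: log10 of the Euclidean first-difference norm."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("mfl requires at least 2 samples")
    return float(np.log10(np.sqrt((np.diff(x) ** 2).sum()) + EPS))


# -- battery ---------------------------------------------------------------

def _zc(x: np.ndarray, fs: float) -> float:
    return float(np.sum(x[:-1] * x[1:] < 0))


def _ssc(x: np.ndarray, fs: float) -> float:
    return float(np.sum((x[1:-1] - x[:-2]) * (x[1:-1] - x[2:]) > 0))


def _skew(x: np.ndarray) -> float:
    """Biased sample skewness m3 / m2^1.5 (0 for zero-variance input)."""
    c = x - x.mean()
    m2 = np.mean(c ** 2)
    return float(np.mean(c ** 3) / m2 ** 1.5) if m2 > 0 else 0.0


def _kurt(x: np.ndarray) -> float:
    """Biased excess kurtosis m4 / m2² − 3 (0 for zero-variance input)."""
    c = x - x.mean()
    m2 = np.mean(c ** 2)
    return float(np.mean(c ** 4) / m2 ** 2 - 3.0) if m2 > 0 else 0.0


def _hjorth_mobility(x: np.ndarray) -> float:
    return float(np.sqrt(np.var(np.diff(x)) / (np.var(x) + EPS)))


def _time_domain_battery() -> dict:
    return {
        "MAV": lambda x, fs: float(np.mean(np.abs(x))),
        "IEMG": lambda x, fs: float(np.sum(np.abs(x))),
        "SSI": lambda x, fs: float(np.sum(x ** 2)),
        "RMS": lambda x, fs: float(np.sqrt(np.mean(x ** 2))),
        "VAR": lambda x, fs: float(np.var(x, ddof=1)),
        "SD": lambda x, fs: float(np.std(x, ddof=1)),
        "WL": lambda x, fs: float(np.sum(np.abs(np.diff(x)))),
        "AAC": lambda x, fs: float(np.mean(np.abs(np.diff(x)))),
        "MAD": lambda x, fs: float(np.median(np.abs(x - np.median(x)))),
        "DASDV": lambda x, fs: dasdv_ldasdv(x)[0],
        "LDASDV": lambda x, fs: dasdv_ldasdv(x)[1],
        "ZC": _zc,
        "SSC": _ssc,
        "WAMP": lambda x, fs: float(np.sum(np.abs(np.diff(x)) > WAMP_THRESHOLD)),
        "MYOP": lambda x, fs: float(np.mean(np.abs(x) > WAMP_THRESHOLD)),
        "LOG": lambda x, fs: float(np.exp(np.mean(np.log(np.abs(x) + EPS)))),
        "MFL": lambda x, fs: mfl(x),
        "MSR": lambda x, fs: float(np.mean(np.sqrt(np.abs(x)))),
        "PEAK": lambda x, fs: float(np.max(np.abs(x))),
        "CREST": lambda x, fs: float(np.max(np.abs(x)) /
                                     (np.sqrt(np.mean(x ** 2)) + EPS)),
        "SKEW": lambda x, fs: _skew(x),
        "KURT": lambda x, fs: _kurt(x),
        "TKEO_MEAN": lambda x, fs: float(np.mean(np.abs(tkeo(x)))),
        "LTKEO": lambda x, fs: ltkeo(x),
        "HJORTH_MOBILITY": lambda x, fs: _hjorth_mobility(x),
        "HJORTH_COMPLEXITY": lambda x, fs: float(
            _hjorth_mobility(np.diff(x)) / (_hjorth_mobility(x) + EPS)),
        "TM3": lambda x, fs: float(np.abs(np.mean(x ** 3))),
        "TM4": lambda x, fs: float(np.mean(x ** 4)),
        "TM5": lambda x, fs: float(np.abs(np.mean(x ** 5))),
    }


# Per-channel PSD cache so the 14 frequency-domain operators in one
# emg_feature_vector call share a single Welch computation.  Keyed by the
# array's object id and cleared as soon as the channel is done.
_SPECTRUM_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _get_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    cached = _SPECTRUM_CACHE.get(id(x))
    return cached if cached is not None else welch_psd(x, fs)


def _freq_domain_battery() -> dict:
    def wrap(fn):
        def op(x, fs):
            freqs, psd = _get_spectrum(x, fs)
            return float(fn(freqs, psd))
        return op

    return {
        "MNF": wrap(mean_frequency),
        "MDF": wrap(median_frequency),
        "PKF": wrap(peak_frequency),
        "TTP": wrap(total_power),
        "MNP": wrap(lambda f, p: np.mean(p)),
        "SM1": wrap(lambda f, p: spectral_moment(f, p, 1)),
        "SM2": wrap(lambda f, p: spectral_moment(f, p, 2)),
        "SM3": wrap(lambda f, p: spectral_moment(f, p, 3)),
        "FR": wrap(lambda f, p: band_power(f, p, BAND_LO, FREQ_SPLIT) /
                   (band_power(f, p, FREQ_SPLIT, BAND_HI) + EPS)),
        "VCF": wrap(lambda f, p: spectral_moment(f, p, 2) / (total_power(f, p) + EPS)
                    - (spectral_moment(f, p, 1) / (total_power(f, p) + EPS)) ** 2),
        "SPECTRAL_ENTROPY": wrap(lambda f, p: spectral_entropy(p)),
        "SEF95": wrap(lambda f, p: spectral_edge(f, p, 0.95)),
        "BP_LOW": wrap(lambda f, p: band_power(f, p, BAND_LO, FREQ_SPLIT) /
                       (total_power(f, p) + EPS)),
        "BP_HIGH": wrap(lambda f, p: band_power(f, p, FREQ_SPLIT, BAND_HI) /
                        (total_power(f, p) + EPS)),
    }


def default_battery() -> dict:
    """The ordered 43-operator battery (name → callable(signal, fs))."""
    battery = _time_domain_battery()
    battery.update(_freq_domain_battery())
    assert len(battery) == 43
    return battery


EMG_FEATURE_NAMES: tuple[str, ...] = tuple(default_battery())


def emg_feature_vector(segment: PhaseSegment,
                       battery: dict | None = None) -> dict[str, float]:
    """All battery features for every channel of a conditioned segment.

    Returns 43 × n_channels named values (258 for the standard six
    channels).  Raises if an operator produces a non-finite value, naming
    the operator and channel.
    """
    battery = battery or default_battery()
    out: dict[str, float] = {}
    for ch_name, x in zip(segment.channel_names, segment.data):
        _SPECTRUM_CACHE[id(x)] = welch_psd(x, segment.fs)
        try:
            for op_name, op in battery.items():
                v = op(x, segment.fs)
                if not np.isfinite(v):
                    raise ValueError(
                        f"operator {op_name!r} on channel {ch_name!r} "
                        f"produced non-finite value {v}"
                    )
                out[f"EMG__{ch_name}__{op_name}"] = v
        finally:
            del _SPECTRUM_CACHE[id(x)]
    return out


def emg_phase_features(segment: PhaseSegment,
                       battery: dict | None = None) -> dict[str, float]:
    """Condition (band-pass) then extract the full battery."""
    return emg_feature_vector(bandpass_emg(segment), battery)
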