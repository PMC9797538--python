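"""Synthetic multimodal cohort generator.

Emulates the phase-dependent statistical structure of a six-phase
VR/platform postural-control protocol so the downstream feature-extraction
and classification stages have a testable input:

* **EEG** (64 channels, 1,024 Hz): 1/f-shaped background plus band-limited
  alpha (8–13 Hz) and low-gamma (30–45 Hz) components.  From the visual
  onset (PRE) onward, occipital low-gamma and frontal/parietal alpha
  amplitude shift by ``visual_onset_eeg``.
* **EMG** (6 channels — TA/GL/SOL × L/R, 1,600 Hz): 15–500 Hz band-limited
  noise amplitude-modulated by a homogeneous Poisson burst process with
  Hann envelopes; burst rate and amplitude scale with platform intensity ×
  ``platform_gain`` and, in POST, with ``post_ap_gain`` (postural
  corrections after the perturbation).
* **CoP** (2 channels, 90 Hz, sensor percentages in [−1, 1]): AR(1)
  (discrete Ornstein–Uhlenbeck) sway per axis; medio-lateral innovation
  variance scales with platform intensity × ``platform_gain``; the
  anterior-posterior innovation variance inflates by ``post_ap_gain`` in
  POST.

With all gains at zero the phases are exchangeable (null model).
Everything is deterministic given (seed, parameters).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .montage import EEG_CHANNELS, OCCIPITAL, FRONTAL_PARIETAL
from .protocol import PLATFORM_INTENSITY, ProtocolTimeline

EMG_CHANNELS = ("TA_L", "TA_R", "GL_L", "GL_R", "SOL_L", "SOL_R")

FS_EEG = 1024.0
FS_EMG = 1600.0
FS_COP = 90.0

#: AR(1) pole of the sway process at 90 Hz (time constant ~0.55 s).
_SWAY_PHI = 0.98
#: Baseline stationary sway SD in sensor units (fraction of half-platform).
_SWAY_BASE_SD = 0.03

_BURST_BASE_RATE = 0.2   # bursts/s at rest
_BURST_RATE_SLOPE = 2.0  # bursts/s per unit (gain × intensity)
_BURST_DUR_S = 0.3
_BURST_AMP_FACTOR = 3.0  # burst RMS relative to baseline EMG noise

_EEG_ALPHA_RMS = 3.0     # µV, baseline alpha component
_EEG_GAMMA_RMS = 1.0     # µV, baseline low-gamma component


@dataclass(frozen=True)
class EffectProfile:
    """Gains controlling the planted phase contrasts.

    All gains are unitless and must be finite and >= 0.  The defaults are
    the package's standard study conditions: they are calibrated so the
    planted medio-lateral sway and EMG burst-energy contrasts have large
    effect sizes (phase-ANOVA eta-squared of roughly 0.4-0.5 for the
    leading CoP/EMG features), while the EEG contrast is a visual-onset
    step only, so EEG separates baseline from the rest but not the motion
    phases from each other.  ``null()`` gives exchangeable phases.
    """

    visual_onset_eeg: float = 1.0
    platform_gain: float = 3.0
    post_ap_gain: float = 2.0
    eeg_noise_uv: float = 10.0
    emg_noise_mv: float = 0.01
    cop_sway_sd: float = _SWAY_BASE_SD

    def __post_init__(self) -> None:
        for name in ("visual_onset_eeg", "platform_gain", "post_ap_gain",
                     "eeg_noise_uv", "emg_noise_mv", "cop_sway_sd"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"EffectProfile.{name} must be finite, got {v}")
            if v < 0:
                raise ValueError(f"EffectProfile.{name} must be >= 0, got {v}")

    @classmethod
    def null(cls) -> "EffectProfile":
        """All gains zero: phase-exchangeable signals."""
        return cls(visual_onset_eeg=0.0, platform_gain=0.0, post_ap_gain=0.0)

    def scaled(self, f_visual: float, f_platform: float, f_post: float) -> "EffectProfile":
        return dataclasses.replace(
            self,
            visual_onset_eeg=self.visual_onset_eeg * f_visual,
            platform_gain=self.platform_gain * f_platform,
            post_ap_gain=self.post_ap_gain * f_post,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MultimodalRecording:
    """Per-subject raw signals with sampling rates and protocol timeline.

    ``eeg`` is 64 × N_e in µV, ``emg`` 6 × N_m in mV, ``cop_raw`` 2 × N_c in
    sensor percentages within [−1, 1] with rows (StaticVR_ML, StaticVR_AP).
    Any modality may be None when generation/loading was restricted.
    When ``cop_starts_after_bl`` is true the CoP trace covers PRE→POST only.
    """

    subject_id: str
    timeline: ProtocolTimeline
    eeg: np.ndarray | None = None
    emg: np.ndarray | None = None
    cop_raw: np.ndarray | None = None
    fs_eeg: float = FS_EEG
    fs_emg: float = FS_EMG
    fs_cop: float = FS_COP
    eeg_channels: tuple[str, ...] = EEG_CHANNELS
    emg_channels: tuple[str, ...] = EMG_CHANNELS
    cop_starts_after_bl: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        total = self.timeline.total_duration
        cop_total = total
        if self.cop_starts_after_bl and "BL" in self.timeline.labels:
            cop_total = total - self.timeline.duration("BL")
        for name, arr, fs, dur, nch in (
            ("eeg", self.eeg, self.fs_eeg, total, len(self.eeg_channels)),
            ("emg", self.emg, self.fs_emg, total, len(self.emg_channels)),
            ("cop_raw", self.cop_raw, self.fs_cop, cop_total, 2),
        ):
            if arr is None:
                continue
            if arr.ndim != 2 or arr.shape[0] != nch:
                raise ValueError(f"{name}: expected {nch} × N array, got {arr.shape}")
            expected = round(dur * fs)
            if abs(arr.shape[1] - expected) > 1:
                raise ValueError(
                    f"{name}: length {arr.shape[1]} inconsistent with "
                    f"{dur} s × {fs} Hz = {expected}"
                )
        if self.cop_raw is not None and np.abs(self.cop_raw).max(initial=0.0) > 1.0:
            raise ValueError("cop_raw values must lie in [-1, 1]")


def _phase_array(timeline: ProtocolTimeline, fs: float, skip_bl: bool = False):
    """Per-sample phase index and the list of (label, start, stop) sample spans."""
    spans = []
    pos = 0
    for lab, dur in timeline.phases:
        if skip_bl and lab == "BL":
            continue
        n = round(dur * fs)
        spans.append((lab, pos, pos + n))
        pos += n
    return spans, pos


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, unit RMS per channel.

    Synthesized in float32 — 64 channels × 5+ minutes is large, and the
    noise floor does not need float64 resolution.
    """
    from scipy.fft import irfft, rfft  # preserves float32, unlike numpy.fft

    white = rng.standard_normal((n_ch, n), dtype=np.float32)
    spec = rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    shape = np.empty(freqs.shape, dtype=np.float32)
    shape[0] = 0.0
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    x = irfft(spec * shape, n=n, axis=1)
    # normalize by the process's *expected* RMS, not the realized one —
    # realized-RMS scaling couples the energies of disjoint analysis
    # windows (their sum is pinned), biasing null-phase contrasts
    expected_rms = np.sqrt(
        (2.0 * (shape[1:-1] ** 2).sum() + shape[-1] ** 2) / n)
    return x / np.float32(expected_rms)


def _band_noise(rng: np.random.Generator, n_ch: int, n: int, lo: float, hi: float,
                fs: float) -> np.ndarray:
    """Band-limited Gaussian noise, unit RMS per channel (float32).

    Synthesized spectrally: independent complex-Gaussian Fourier
    coefficients inside [lo, hi), zero outside — exactly band-limited.
    """
    from scipy.fft import irfft

    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= lo) & (freqs < hi)
    mask[0] = mask[-1] = False  # keep DC/Nyquist out of the band
    k = int(mask.sum())
    if k == 0:
        raise ValueError(f"band [{lo}, {hi}) Hz is empty at n={n}, fs={fs}")
    spec = np.zeros((n_ch, freqs.size), dtype=np.complex64)
    vals = rng.standard_normal((n_ch, k, 2), dtype=np.float32)
    spec[:, mask] = vals[..., 0] + 1j * vals[..., 1]
    x = irfft(spec, n=n, axis=1)
    # expected-RMS normalization (see _pink_noise): unit RMS in expectation
    return x * np.float32(n / (2.0 * np.sqrt(k)))


def _gen_eeg(rng, timeline, effects) -> np.ndarray:
    spans, n = _phase_array(timeline, FS_EEG)
    n_ch = len(EEG_CHANNELS)
    eeg = np.float32(effects.eeg_noise_uv) * _pink_noise(rng, n_ch, n)
    alpha = _band_noise(rng, n_ch, n, 8.0, 13.0, FS_EEG)
    gamma = _band_noise(rng, n_ch, n, 30.0, 45.0, FS_EEG)

    is_occ = np.array([c in OCCIPITAL for c in EEG_CHANNELS])
    is_fp = np.array([c in FRONTAL_PARIETAL for c in EEG_CHANNELS])
    alpha *= _EEG_ALPHA_RMS
    gamma *= _EEG_GAMMA_RMS
    g = np.float32(effects.visual_onset_eeg)
    for lab, a, b in spans:
        if lab != "BL":  # visual stimulation on from PRE onward
            alpha[is_fp, a:b] *= 1.0 + g
            gamma[is_occ, a:b] *= 1.0 + g
    eeg += alpha
    eeg += gamma
    return eeg


def _gen_emg(rng, timeline, effects) -> np.ndarray:
    spans, n = _phase_array(timeline, FS_EMG)
    n_ch = len(EMG_CHANNELS)
    base = effects.emg_noise_mv * _band_noise(rng, n_ch, n, 15.0, 500.0, FS_EMG)
    carrier = _band_noise(rng, n_ch, n, 15.0, 500.0, FS_EMG)

    burst_len = round(_BURST_DUR_S * FS_EMG)
    win = np.hanning(burst_len)
    envelope = np.zeros((n_ch, n))
    for lab, a, b in spans:
        drive = effects.platform_gain * PLATFORM_INTENSITY[lab]
        if lab == "POST":
            drive += effects.post_ap_gain
        rate = _BURST_BASE_RATE + _BURST_RATE_SLOPE * drive
        amp = _BURST_AMP_FACTOR * effects.emg_noise_mv * (1.0 + drive)
        dur_s = (b - a) / FS_EMG
        for ch in range(n_ch):
            k = rng.poisson(rate * dur_s)
            starts = a + (rng.random(k) * (b - a - burst_len)).astype(int)
            for s in starts:
                envelope[ch, s:s + burst_len] += amp * win
    return base + envelope * carrier


#: Wave-band of the platform-driven sway component, Hz (scaled per subject).
_WAVE_BAND = (0.5, 2.5)
#: Log-SD of the per-subject wave-frequency factor (individual sway tempo).
_WAVE_FREQ_JITTER = 0.3
#: Log-SD of the per-subject AP response amplitude (AP sway is the most
#: individual part of the response; ML is driven by the platform).
_AP_STYLE_JITTER = 0.6


def _gen_cop(rng, timeline, effects, cop_starts_after_bl) -> np.ndarray:
    """Quiet-stance AR(1) sway plus a platform-driven wave-band component.

    The background is a fixed AR(1) process per axis (discrete
    Ornstein–Uhlenbeck, pole 0.98 at 90 Hz).  The planted phase effect is
    an additive band-limited sway component whose *amplitude* scales with
    platform intensity × ``platform_gain`` on ML (and, in POST, with
    ``post_ap_gain`` on AP), while its frequency band varies between
    subjects — so the phase contrast lands in the sway-dispersion
    statistics (RMS distance, SD) rather than in sway-velocity or
    sway-frequency measures, which inherit the between-subject tempo
    spread.
    """
    spans, n = _phase_array(timeline, FS_COP, skip_bl=cop_starts_after_bl)
    sd0 = effects.cop_sway_sd
    # per-subject sway style (drawn first: fixed rng order = determinism);
    # both factors only touch the driven component, so the null model
    # (all gains zero) stays phase- and subject-exchangeable
    u = math.exp(rng.normal(0.0, _WAVE_FREQ_JITTER))
    ap_style = math.exp(rng.normal(0.0, _AP_STYLE_JITTER))
    # background sway, continuous across phases, stationary initialization
    innov = sd0 * math.sqrt(1.0 - _SWAY_PHI**2)
    eps = rng.standard_normal((2, n)) * innov
    state = rng.standard_normal(2) * sd0
    cop = np.empty((2, n))
    for ax in range(2):
        cop[ax], _ = signal.lfilter([1.0], [1.0, -_SWAY_PHI], eps[ax],
                                    zi=[_SWAY_PHI * state[ax]])
    # platform/scene-driven wave component, amplitude stepped per phase
    wave = _band_noise(rng, 2, n, _WAVE_BAND[0] * u, _WAVE_BAND[1] * u,
                       FS_COP).astype(float)
    amp = np.zeros((2, n))
    for lab, a, b in spans:
        drive = effects.platform_gain * PLATFORM_INTENSITY[lab]
        amp[0, a:b] = sd0 * drive
        amp[1, a:b] = sd0 * ap_style * (
            0.3 * drive + (effects.post_ap_gain if lab == "POST" else 0.0))
    cop += amp * wave
    return np.clip(cop, -1.0, 1.0)


ALL_MODALITIES = ("eeg", "emg", "cop")


def generate_recording(subject_id: str,
                       timeline: ProtocolTimeline | None = None,
                       effects: EffectProfile | None = None,
                       seed: int = 0,
                       modalities: tuple[str, ...] = ALL_MODALITIES,
                       cop_starts_after_bl: bool = True) -> MultimodalRecording:
    """Generate one subject's multimodal recording.

    Deterministic given ``(seed, parameters)``; each modality draws from its
    own child stream so restricting ``modalities`` does not change the
    signals of the ones that are generated.
    """
    timeline = timeline or ProtocolTimeline.default()
    effects = effects or EffectProfile()
    unknown = set(modalities) - set(ALL_MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities: {sorted(unknown)}")
    ss = np.random.SeedSequence(seed)
    streams = dict(zip(ALL_MODALITIES, ss.spawn(3)))
    eeg = emg = cop = None
    if "eeg" in modalities:
        eeg = _gen_eeg(np.random.default_rng(streams["eeg"]), timeline, effects)
    if "emg" in modalities:
        emg = _gen_emg(np.random.default_rng(streams["emg"]), timeline, effects)
    if "cop" in modalities:
        cop = _gen_cop(np.random.default_rng(streams["cop"]), timeline, effects,
                       cop_starts_after_bl)
    return MultimodalRecording(
        subject_id=subject_id, timeline=timeline, eeg=eeg, emg=emg, cop_raw=cop,
        cop_starts_after_bl=cop_starts_after_bl, seed=seed,
    )


def cohort_seeds(n_subjects: int, seed: int) -> list[int]:
    """Reproducible per-subject seeds derived from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subjects)]


def _jittered_effects(effects: EffectProfile, rng: np.random.Generator) -> EffectProfile:
    # Subject-level heterogeneity multiplies the response gains only (log-normal,
    # sigma 0.2); baseline noise floors are shared so the null model stays
    # exchangeable across subjects and phases.
    f = np.exp(rng.normal(0.0, 0.2, size=3))
    return effects.scaled(*f)


def iter_cohort(n_subjects: int,
                effects: EffectProfile | None = None,
                seed: int = 0,
                timeline: ProtocolTimeline | None = None,
                modalities: tuple[str, ...] = ALL_MODALITIES,
                subject_jitter: bool = True):
    """Lazily yield the cohort's recordings (memory-friendly for large n)."""
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (train/test splits impossible)")
    effects = effects or EffectProfile()
    seeds = cohort_seeds(n_subjects, seed)
    jrng = np.random.default_rng(np.random.SeedSequence((seed, 0xA11CE)))
    for i, s in enumerate(seeds):
        eff_i = _jittered_effects(effects, jrng) if subject_jitter else effects
        yield generate_recording(f"S{i + 1:03d}", timeline, eff_i, seed=s,
                                 modalities=modalities)


def generate_cohort(n_subjects: int = 172,
                    effects: EffectProfile | None = None,
                    seed: int = 0,
                    timeline: ProtocolTimeline | None = None,
                    modalities: tuple[str, ...] = ALL_MODALITIES,
                    subject_jitter: bool = True) -> list[MultimodalRecording]:
    """Generate the full cohort as a list (default size 172 subjects)."""
    return list(iter_cohort(n_subjects, effects, seed, timeline, modalities,
                            subject_jitter))


# ---------------------------------------------------------------------------
# Disk round-trip: one directory per subject, column-text files + JSON sidecar.

def save_recording(rec: MultimodalRecording, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": rec.subject_id,
        "timeline": rec.timeline.to_dict(),
        "fs": {"eeg": rec.fs_eeg, "emg": rec.fs_emg, "cop": rec.fs_cop},
        "eeg_channels": list(rec.eeg_channels),
        "emg_channels": list(rec.emg_channels),
        "cop_starts_after_bl": rec.cop_starts_after_bl,
        "seed": rec.seed,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    for name, arr, fs, chans in (
        ("eeg", rec.eeg, rec.fs_eeg, rec.eeg_channels),
        ("emg", rec.emg, rec.fs_emg, rec.emg_channels),
        ("cop", rec.cop_raw, rec.fs_cop, ("StaticVR_ML", "StaticVR_AP")),
    ):
        if arr is None:
            continue
        t = np.arange(arr.shape[1]) / fs
        np.savetxt(d / f"{name}.tsv", np.column_stack([t, arr.T]),
                   fmt="%.6g", delimiter="\t",
                   header="time\t" + "\t".join(chans), comments="")


def load_recording(directory: str | Path) -> MultimodalRecording:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    arrays: dict[str, np.ndarray | None] = {}
    for name in ("eeg", "emg", "cop"):
        p = d / f"{name}.tsv"
        arrays[name] = np.loadtxt(p, delimiter="\t", skiprows=1).T[1:] if p.exists() else None
    return MultimodalRecording(
        subject_id=meta["subject_id"],
        timeline=ProtocolTimeline.from_dict(meta["timeline"]),
        eeg=arrays["eeg"], emg=arrays["emg"], cop_raw=arrays["cop"],
        fs_eeg=meta["fs"]["eeg"], fs_emg=meta["fs"]["emg"], fs_cop=meta["fs"]["cop"],
        eeg_channels=tuple(meta["eeg_channels"]),
        emg_channels=tuple(meta["emg_channels"]),
        cop_starts_after_bl=meta["cop_starts_after_bl"],
        seed=meta["seed"],
    )


def manifest_hash(directory: str | Path) -> str:
    """SHA-256 over the subject data files, for drift detection.

    Logs and the manifest itself are excluded (they carry timestamps).
    """
    h = hashlib.sha256()
    for p in sorted(Path(directory).rglob("*")):
        if p.is_file() and p.suffix != ".log" and p.name != "manifest.json":
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
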