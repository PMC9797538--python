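"""Cut each modality into its per-phase analysis windows.

Trimming rules: EEG drops the first and last 5 s of every phase, and for
the 2-min baseline only the last 60 s are retained before trimming (so
50 s of BL and 30 s of each 40-s phase are analyzed).  EMG keeps the
central 20 s of each phase (for BL: the central 20 s of its last 60 s),
which removes the phase transitions.  CoP recording starts only after BL,
so CoP has five full 40-s phase windows and no BL segment.

Sample indexing uses half-open, 0-based intervals: a window (start_s,
end_s) at rate fs covers samples [round(start_s*fs), round(end_s*fs)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import MultimodalRecording

EEG_TRIM_S = 5.0
BL_RETAIN_S = 60.0
EMG_WINDOW_S = 20.0
MIN_EEG_WINDOW_S = 10.0

COP_PHASES = ("PRE", "P25", "P50", "P75", "POST")


@dataclass
class PhaseSegment:
    """One modality's samples for one labeled phase window.

    ``window`` is (start_s, end_s) relative to the phase onset.
    """

    label: str
    modality: str  # EEG | EMG | COP
    data: np.ndarray  # channels × samples
    fs: float
    window: tuple[float, float]
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        start, end = self.window
        if not end > start:
            raise ValueError(f"window end {end} must exceed start {start}")
        expected = round((end - start) * self.fs)
        if self.data.shape[1] != expected:
            raise ValueError(
                f"segment {self.label}/{self.modality}: {self.data.shape[1]} samples, "
                f"expected round(({end} - {start}) × {self.fs}) = {expected}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _slice(arr: np.ndarray, fs: float, t0: float, t1: float) -> np.ndarray:
    return arr[:, round(t0 * fs):round(t1 * fs)]


def segment_eeg(rec: MultimodalRecording) -> list[PhaseSegment]:
    """Six EEG segments in protocol order, trimmed per the rules above."""
    if rec.eeg is None:
        raise ValueError("recording has no EEG")
    out = []
    for lab, dur in rec.timeline.phases:
        if lab == "BL":
            w0 = max(0.0, dur - BL_RETAIN_S) + EEG_TRIM_S
        else:
            w0 = EEG_TRIM_S
        w1 = dur - EEG_TRIM_S
        if w1 - w0 < MIN_EEG_WINDOW_S:
            raise ValueError(
                f"phase {lab!r}: {max(w1 - w0, 0.0):.1f} s left after trimming "
                f"(need >= {MIN_EEG_WINDOW_S:.0f} s)"
            )
        onset = rec.timeline.onset(lab)
        out.append(PhaseSegment(
            label=lab, modality="EEG",
            data=_slice(rec.eeg, rec.fs_eeg, onset + w0, onset + w1),
            fs=rec.fs_eeg, window=(w0, w1), channel_names=rec.eeg_channels,
        ))
    return out


def segment_emg(rec: MultimodalRecording) -> list[PhaseSegment]:
    """Central 20-s EMG window of every phase (BL: within its last 60 s)."""
    if rec.emg is None:
        raise ValueError("recording has no EMG")
    out = []
    for lab, dur in rec.timeline.phases:
        if lab == "BL":
            a, b = max(0.0, dur - BL_RETAIN_S), dur
        else:
            a, b = 0.0, dur
        if b - a < EMG_WINDOW_S:
            raise ValueError(
                f"phase {lab!r}: {b - a:.1f} s available, need >= {EMG_WINDOW_S:.0f} s"
            )
        c = 0.5 * (a + b)
        w0, w1 = c - EMG_WINDOW_S / 2, c + EMG_WINDOW_S / 2
        onset = rec.timeline.onset(lab)
        out.append(PhaseSegment(
            label=lab, modality="EMG",
            data=_slice(rec.emg, rec.fs_emg, onset + w0, onset + w1),
            fs=rec.fs_emg, window=(w0, w1), channel_names=rec.emg_channels,
        ))
    return out


def segment_cop(rec: MultimodalRecording) -> list[PhaseSegment]:
    """Five full-phase CoP segments (PRE, P25, P50, P75, POST); BL omitted."""
    if rec.cop_raw is None:
        raise ValueError("recording has no CoP")
    missing = [p for p in COP_PHASES if p not in rec.timeline.labels]
    if missing:
        raise ValueError(f"timeline lacks phases required for CoP: {missing}")
    offset = 0.0
    if rec.cop_starts_after_bl and "BL" in rec.timeline.labels:
        offset = rec.timeline.onset("PRE")
    out = []
    for lab, dur in rec.timeline.phases:
        if lab == "BL":
            continue
        onset = rec.timeline.onset(lab) - offset
        out.append(PhaseSegment(
            label=lab, modality="COP",
            data=_slice(rec.cop_raw, rec.fs_cop, onset, onset + dur),
            fs=rec.fs_cop, window=(0.0, dur),
            channel_names=("StaticVR_ML", "StaticVR_AP"),
        ))
    return out


def segments_by_label(segments: list[PhaseSegment]) -> dict[str, PhaseSegment]:
    """Address segments by phase label; a missing phase raises KeyError."""
    return {s.label: s for s in segments}
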