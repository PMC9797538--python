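"""Per-recording feature extraction and cohort feature tables.

A full non-baseline phase yields 25 EEG + 258 EMG + 35 CoP = 318 named
features; BL has no CoP (the platform recording starts only after
baseline), hence 283.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .cop import PlatformGeometry, cop_phase_features
from .eeg import eeg_phase_features
from .emg import emg_phase_features
from .segmentation import segment_cop, segment_eeg, segment_emg
from .synth import MultimodalRecording

MODALITIES = ("EEG", "EMG", "COP")


def extract_features(rec: MultimodalRecording,
                     modalities: Iterable[str] = MODALITIES,
                     geometry: PlatformGeometry | None = None) -> pd.DataFrame:
    """Feature table for one recording: rows = phases, columns = features."""
    modalities = tuple(m.upper() for m in modalities)
    unknown = set(modalities) - set(MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities: {sorted(unknown)}")
    rows: dict[str, dict[str, float]] = {lab: {} for lab in rec.timeline.labels}
    if "EEG" in modalities:
        for seg in segment_eeg(rec):
            rows[seg.label].update(eeg_phase_features(seg))
    if "EMG" in modalities:
        for seg in segment_emg(rec):
            rows[seg.label].update(emg_phase_features(seg))
    if "COP" in modalities:
        for seg in segment_cop(rec):
            rows[seg.label].update(cop_phase_features(seg, geometry))
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "phase"
    return df


def cohort_feature_table(recordings: Iterable[MultimodalRecording],
                         modalities: Iterable[str] = MODALITIES,
                         geometry: PlatformGeometry | None = None) -> pd.DataFrame:
    """Long table over a cohort: columns subject_id, phase, features.

    Accepts any iterable (including a lazy generator, so large cohorts never
    need to be in memory at once).
    """
    frames = []
    for rec in recordings:
        df = extract_features(rec, modalities, geometry).reset_index()
        df.insert(0, "subject_id", rec.subject_id)
        frames.append(df)
    if not frames:
        raise ValueError("no recordings supplied")
    return pd.concat(frames, ignore_index=True)
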