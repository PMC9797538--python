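"""Shared fixtures: one fully generated recording and its feature table.

Expensive objects are session-scoped; everything is generated at test time
from fixed seeds (no stored fixtures).
"""

import numpy as np
import pytest

import postphase as pp


@pytest.fixture(scope="session")
def strong_recording() -> pp.MultimodalRecording:
    """One subject under the default (strong-effect) study conditions."""
    return pp.generate_recording("S001", seed=7)


@pytest.fixture(scope="session")
def strong_features(strong_recording):
    """Full 318-column per-phase feature table for the strong recording."""
    return pp.extract_features(strong_recording)


@pytest.fixture(scope="session")
def emg_cop_cohort_table():
    """Long feature table for a small strong-effect EMG+CoP cohort (n=8)."""
    recs = pp.iter_cohort(8, seed=3, modalities=("emg", "cop"))
    return pp.cohort_feature_table(recs, ("EMG", "COP"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
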