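"""EMG conditioning and the 43-operator battery: closed forms, scaling laws,
spectral oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from postphase.emg import (EPS, EMG_FEATURE_NAMES, bandpass_emg, dasdv_ldasdv,
                           default_battery, emg_feature_vector,
                           emg_phase_features, ltkeo, mfl, tkeo)
from postphase.segmentation import PhaseSegment

FS = 1600.0


def _segment(data, fs=FS, names=None):
    data = np.atleast_2d(data)
    names = names or tuple(f"m{i}" for i in range(data.shape[0]))
    return PhaseSegment("PRE", "EMG", data, fs, (0.0, data.shape[1] / fs), names)


def _tone(freq, dur=4.0, fs=FS):
    return np.sin(2 * np.pi * freq * np.arange(int(dur * fs)) / fs)


class TestTkeo:
    def test_constant_gives_zeros(self):
        assert np.allclose(tkeo(np.full(100, 3.7)), 0.0)

    def test_hand_arithmetic(self):
        assert np.allclose(tkeo(np.array([1.0, 2.0, 4.0])), [0.0])

    def test_sinusoid_identity(self):
        # Ψ[A sin(ωn)] = A² sin²(ω) at every interior sample
        A, w = 2.0, 0.3
        x = A * np.sin(w * np.arange(200))
        assert np.allclose(tkeo(x), A**2 * np.sin(w) ** 2, atol=1e-10)

    def test_output_length_and_minimum(self):
        assert tkeo(np.arange(10.0)).size == 8
        with pytest.raises(ValueError):
            tkeo(np.array([1.0, 2.0]))

    @given(st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_ltkeo_scaling_law(self, c):
        # Ψ is homogeneous of degree 2 → ltkeo(c·x) = ltkeo(x) + 2 ln c
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        assert ltkeo(c * x) == pytest.approx(ltkeo(x) + 2 * np.log(c), abs=1e-6)

    def test_ltkeo_constant_is_log_eps(self):
        assert ltkeo(np.full(50, 2.0)) == pytest.approx(np.log(EPS))

    def test_ltkeo_bursts_exceed_quiet_noise(self, rng):
        quiet = rng.standard_normal(8000)
        env = np.ones(8000)
        env[2000:2400] += 8.0 * np.hanning(400)
        burst = quiet * env
        assert ltkeo(burst) > ltkeo(quiet)


class TestDifferenceOperators:
    def test_dasdv_ramp_equals_step(self):
        d, l = dasdv_ldasdv(np.arange(0.0, 50.0, 0.5))
        assert d == pytest.approx(0.5)
        assert l == pytest.approx(np.log(0.5 + EPS))

    def test_dasdv_alternating(self):
        x = np.tile([1.5, -1.5], 50)
        assert dasdv_ldasdv(x)[0] == pytest.approx(3.0, rel=1e-2)

    def test_dasdv_constant(self):
        d, l = dasdv_ldasdv(np.zeros(10))
        assert d == 0.0
        assert l == pytest.approx(np.log(EPS))

    def test_mfl_ramp_closed_form(self):
        n, step = 101, 0.25
        x = np.arange(n) * step
        assert mfl(x) == pytest.approx(np.log10(step * np.sqrt(n - 1)))

    def test_mfl_constant_is_log10_eps(self):
        assert mfl(np.zeros(10)) == pytest.approx(np.log10(EPS))

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_mfl_dasdv_identity(self, seed):
        # mfl = 0.5·log10(N−1) + log10(DASDV) for any non-degenerate signal
        x = np.random.default_rng(seed).standard_normal(64)
        d, _ = dasdv_ldasdv(x)
        assert mfl(x) == pytest.approx(0.5 * np.log10(x.size - 1) + np.log10(d),
                                       abs=1e-9)

    def test_minimum_lengths(self):
        with pytest.raises(ValueError):
            dasdv_ldasdv(np.array([1.0]))
        with pytest.raises(ValueError):
            mfl(np.array([1.0]))


class TestBandpass:
    def test_drift_attenuated_20db(self):
        out = bandpass_emg(_segment(_tone(5.0)))
        assert np.sqrt(np.mean(out.data**2)) < 0.1 / np.sqrt(2)

    def test_passband_preserved(self):
        seg = _segment(_tone(100.0))
        out = bandpass_emg(seg)
        sl = slice(800, -800)
        ratio = (np.sqrt(np.mean(out.data[:, sl] ** 2)) /
                 np.sqrt(np.mean(seg.data[:, sl] ** 2)))
        assert abs(ratio - 1.0) < 0.05

    def test_zero_in_zero_out(self):
        out = bandpass_emg(_segment(np.zeros(4000)))
        assert np.allclose(out.data, 0.0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="1,000"):
            bandpass_emg(_segment(np.zeros(4000), fs=1000.0))


class TestBattery:
    def test_exactly_43_uniquely_named_operators(self):
        battery = default_battery()
        assert len(battery) == 43
        assert len(set(battery)) == 43
        for required in ("TKEO_MEAN", "LTKEO", "DASDV", "LDASDV", "MFL",
                         "MAV", "RMS", "WL", "VAR", "ZC", "SSC", "WAMP",
                         "IEMG", "LOG", "AAC", "SKEW", "KURT", "MNF", "MDF",
                         "PKF", "TTP"):
            assert required in battery

    def test_258_features_per_six_channel_segment(self, rng):
        seg = _segment(rng.standard_normal((6, 8000)),
                       names=("TA_L", "TA_R", "GL_L", "GL_R", "SOL_L", "SOL_R"))
        feats = emg_feature_vector(seg)
        assert len(feats) == 258
        assert sum(k.startswith("EMG__TA_R__") for k in feats) == 43
        assert all(np.isfinite(v) for v in feats.values())

    def test_nonfinite_operator_named_in_error(self, rng):
        bad = dict(default_battery())
        bad["MAV"] = lambda x, fs: float("nan")
        seg = _segment(rng.standard_normal((1, 1000)), names=("TA_L",))
        with pytest.raises(ValueError, match="MAV.*TA_L"):
            emg_feature_vector(seg, bad)

    @given(st.floats(0.5, 50.0))
    @settings(deadline=None, max_examples=10, derandomize=True)
    def test_amplitude_scaling_laws(self, c):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(2000)
        b = default_battery()
        for name in ("MAV", "RMS", "DASDV"):
            assert b[name](c * x, FS) == pytest.approx(c * b[name](x, FS),
                                                       rel=1e-9)
        for name in ("ZC", "SSC"):
            assert b[name](c * x, FS) == b[name](x, FS)
        assert b["LTKEO"](c * x, FS) == pytest.approx(
            b["LTKEO"](x, FS) + 2 * np.log(c), abs=1e-6)

    def test_spectral_features_against_cumsum_oracle(self, rng):
        from postphase.spectral import welch_psd
        x = rng.standard_normal(32000)
        b = default_battery()
        mnf, mdf = b["MNF"](x, FS), b["MDF"](x, FS)
        freqs, psd = welch_psd(x, FS)
        assert 0 < mnf <= freqs[-1]
        # MDF splits the power mass in half (brute-force cumulative sum)
        below = psd[freqs <= mdf].sum()
        assert abs(below / psd.sum() - 0.5) < 0.01

    def test_battery_finite_on_generator_output(self, strong_features):
        emg_cols = [c for c in strong_features.columns if c.startswith("EMG__")]
        assert len(emg_cols) == 258
        assert np.isfinite(strong_features[emg_cols].to_numpy()).all()

    def test_ltkeo_separates_baseline_from_post(self, strong_features):
        # burst energy rises after the perturbation (platform off, sea on)
        for side in ("L", "R"):
            assert (strong_features.loc["POST", f"EMG__TA_{side}__LTKEO"] >
                    strong_features.loc["BL", f"EMG__TA_{side}__LTKEO"])


def test_phase_features_conditions_then_extracts(rng):
    seg = _segment(rng.standard_normal((2, 4000)), names=("TA_L", "TA_R"))
    feats = emg_phase_features(seg)
    assert len(feats) == 86
    assert set(EMG_FEATURE_NAMES) == set(default_battery())
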