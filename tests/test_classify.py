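"""Merging configurations, splitting, the model family, and evaluation."""

import numpy as np
import pandas as pd
import pytest

import postphase as pp
from postphase.classify import (MERGE_CONFIGS, MergeConfig, PhaseClassifier,
                                _macro_auc, assemble_table, evaluate,
                                make_models, split, train_models)


def _numeric_table(rng, n_subjects=30, n_classes=3, n_features=6,
                   effect=0.0, prefix="EMG__m__f"):
    """Balanced (subject, class) table with optional planted class shift."""
    rows = []
    for s in range(n_subjects):
        for k in range(n_classes):
            feats = rng.standard_normal(n_features) + effect * k
            rows.append({"subject_id": f"s{s:02d}", "label": f"C{k}",
                         **{f"{prefix}{j}": feats[j] for j in range(n_features)}})
    return pd.DataFrame(rows)


class TestMergeConfigs:
    def test_standard_configurations(self):
        assert MERGE_CONFIGS["six_phase"].n_classes == 6
        assert MERGE_CONFIGS["five_phase"].used_phases == \
            ("PRE", "P25", "P50", "P75", "POST")
        assert dict(MERGE_CONFIGS["four_phase_movement"].groups)["MOVEMENT"] \
            == ("P25", "P50", "P75")
        assert dict(MERGE_CONFIGS["binary_bl"].groups)["NOT_BL"] == \
            ("PRE", "P25", "P50", "P75", "POST")

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="several groups"):
            MergeConfig("bad", (("A", ("PRE",)), ("B", ("PRE", "POST"))))


class TestAssemble:
    def test_five_phase_emg_cop_has_293_columns(self, emg_cop_cohort_table):
        table = assemble_table(emg_cop_cohort_table, "five_phase",
                               ("EMG", "COP"))
        feat_cols = [c for c in table.columns
                     if c not in ("subject_id", "label")]
        assert len(feat_cols) == 258 + 35
        assert not table[feat_cols].isna().any().any()
        # one row per (subject, class)
        assert len(table) == 8 * 5

    def test_binary_merge_averages_constituents(self, emg_cop_cohort_table):
        table = assemble_table(emg_cop_cohort_table, "binary_bl", ("EMG",))
        assert sorted(table["label"].unique()) == ["BL", "NOT_BL"]
        assert len(table) == 16
        col = "EMG__TA_R__RMS"
        long = emg_cop_cohort_table
        s0 = long["subject_id"].iloc[0]
        manual = long[(long.subject_id == s0) & (long.phase != "BL")][col].mean()
        got = table[(table.subject_id == s0) &
                    (table.label == "NOT_BL")][col].iloc[0]
        assert got == pytest.approx(manual)

    def test_merge_of_identical_vectors_is_identity(self):
        rows = []
        for phase in ("P25", "P50", "P75"):
            rows.append({"subject_id": "s0", "phase": phase, "EMG__m__f": 1.5})
        long = pd.DataFrame(rows)
        merge = MergeConfig("m", (("MOVEMENT", ("P25", "P50", "P75")),))
        table = assemble_table(long, merge, ("EMG",))
        assert table["EMG__m__f"].iloc[0] == 1.5

    def test_cop_with_bl_rejected(self, emg_cop_cohort_table):
        for name in ("six_phase", "binary_bl", "four_phase_movement"):
            with pytest.raises(ValueError, match="BL"):
                assemble_table(emg_cop_cohort_table, name, ("EMG", "COP"))

    def test_missing_phase_rejected(self, emg_cop_cohort_table):
        partial = emg_cop_cohort_table[emg_cop_cohort_table.phase != "POST"]
        with pytest.raises(ValueError, match="POST"):
            assemble_table(partial, "five_phase", ("EMG",))


class TestSplit:
    def test_fraction_and_stratification(self, rng):
        table = _numeric_table(rng, n_subjects=50)
        train, test = split(table, 0.2, seed=1)
        assert test["subject_id"].nunique() == 10
        # balanced design → per-class 80/20
        assert (test.groupby("label").size() == 10).all()
        assert (train.groupby("label").size() == 40).all()

    def test_group_by_subject_contract(self, rng):
        table = _numeric_table(rng)
        train, test = split(table, 0.2, seed=3, group_by_subject=True)
        assert not set(train.subject_id) & set(test.subject_id)

    def test_row_level_split_allows_subject_overlap(self, rng):
        table = _numeric_table(rng)
        train, test = split(table, 0.2, seed=3, group_by_subject=False)
        assert (test.groupby("label").size() == 6).all()

    def test_deterministic(self, rng):
        table = _numeric_table(rng)
        a = split(table, 0.2, seed=5)[1]
        b = split(table, 0.2, seed=5)[1]
        pd.testing.assert_frame_equal(a, b)

    def test_bad_fraction_rejected(self, rng):
        with pytest.raises(ValueError, match="fraction"):
            split(_numeric_table(rng), 1.0, seed=0)


class TestModels:
    def test_separable_data_reaches_high_cv_accuracy(self, rng):
        train = _numeric_table(rng, n_subjects=40, effect=4.0)
        per_model, best_name, best = train_models(train, cv_folds=5, seed=0)
        assert per_model["validation_accuracy"].max() >= 95.0
        assert best_name in per_model.index

    def test_permuted_labels_give_chance_accuracy(self, rng):
        train = _numeric_table(rng, n_subjects=40, effect=4.0)
        train["label"] = rng.permutation(train["label"].to_numpy())
        per_model, _, _ = train_models(train, cv_folds=5, seed=0)
        acc = per_model["validation_accuracy"].to_numpy() / 100.0
        n = len(train)
        band = 1.96 * np.sqrt((1 / 3) * (2 / 3) / n)
        assert np.all(np.abs(acc - 1 / 3) < band + 0.1)

    def test_subspace_ensemble_degenerates_at_p_1(self, rng):
        models = make_models(1, seed=0)
        assert models["subspace_discriminant"]["clf"].max_features == 1
        table = _numeric_table(rng, n_features=1, effect=3.0)
        per_model, _, _ = train_models(table, cv_folds=3, seed=0)
        assert np.isfinite(per_model["validation_accuracy"]).all()

    def test_training_ignores_test_labels(self, rng):
        # no leakage: the fitted model cannot depend on the test table at all
        train = _numeric_table(rng, n_subjects=20, effect=2.0)
        a = train_models(train, cv_folds=3, seed=0)[0]
        b = train_models(train.copy(), cv_folds=3, seed=0)[0]
        pd.testing.assert_frame_equal(a, b)


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        train = _numeric_table(rng, n_subjects=30, effect=6.0)
        test = _numeric_table(rng, n_subjects=10, effect=6.0)
        _, _, best = train_models(train, cv_folds=3, seed=0)
        ev = evaluate(best, test)
        assert ev["test_accuracy"] == 100.0
        conf = ev["confusion"].to_numpy()
        assert np.all(conf == np.diag(np.diag(conf)))
        assert (ev["tpr"] == 100.0).all()
        assert (ev["fnr"] == 0.0).all()
        assert np.allclose(ev["tpr"] + ev["fnr"], 100.0)

    def test_feature_mismatch_rejected(self, rng):
        train = _numeric_table(rng)
        _, _, best = train_models(train, cv_folds=3, seed=0)
        test = train.rename(columns={"EMG__m__f0": "EMG__m__zzz"})
        with pytest.raises(ValueError, match="mismatch"):
            evaluate(best, test)

    def test_random_scorer_auc_near_half(self, rng):
        y = np.repeat(["A", "B", "C"], 400)
        scores = rng.standard_normal((1200, 3))
        auc = _macro_auc(y, scores, np.array(["A", "B", "C"]))
        assert abs(auc - 0.5) < 0.05


@pytest.fixture(scope="module")
def small_run():
    recs = pp.iter_cohort(8, seed=3, modalities=("emg", "cop"))
    model = PhaseClassifier.from_cohort(recs, "five_phase", ("EMG", "COP"),
                                        cv_folds=3)
    return model.fit(seed=3)


class TestEndToEnd:
    def test_structural_report(self, small_run):
        res = small_run
        assert res.n_features == 293
        assert res.confusion.shape == (5, 5)
        assert 0 <= res.test_accuracy <= 100
        assert 0 <= res.auc_test <= 1
        # 8 subjects × 0.2 → 2 held-out subjects, 5 rows each
        assert res.confusion.to_numpy().sum() == 10

    def test_summary_mentions_key_numbers(self, small_run):
        text = small_run.summary()
        assert "five_phase" in text
        assert "EMG+COP" in text
        assert f"{small_run.test_accuracy:5.1f}" in text

    def test_report_roundtrip_deterministic(self):
        def run():
            recs = pp.iter_cohort(6, seed=4, modalities=("cop",))
            return pp.run_configuration(recs, "five_phase", ("COP",),
                                        seed=4, cv_folds=3).to_json()
        assert run() == run()

    def test_standard_nine_row_grid(self):
        # the default report grid: biosignal set × merge configuration
        from postphase.config import RunConfig
        from postphase.pipeline import cohort_feature_table

        long = cohort_feature_table(pp.iter_cohort(5, seed=9))
        grid = RunConfig().grid
        assert len(grid) == 9
        reports = []
        for merge_name, modalities in grid:
            table = assemble_table(long, merge_name, modalities)
            res = PhaseClassifier(table, merge_name=merge_name,
                                  modalities=modalities,
                                  cv_folds=2).fit(seed=9)
            reports.append(res)
            k = len(MERGE_CONFIGS[merge_name].groups)
            assert res.confusion.shape == (k, k)
        assert len(reports) == 9
        # CoP-bearing rows never include BL
        for res in reports:
            if "COP" in res.modalities:
                assert "BL" not in res.confusion.index

    def test_binary_eeg_confusion_is_2x2(self):
        recs = pp.iter_cohort(4, seed=6, modalities=("emg",))
        res = pp.run_configuration(recs, "binary_bl", ("EMG",), seed=6,
                                   cv_folds=2)
        assert res.confusion.shape == (2, 2)
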