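"""Phase classification under the protocol's merging configurations.

The experiment's six phases can be merged into coarser class sets (the
three motion phases averaged into one "movement" class; everything but
baseline averaged into a single class for a binary baseline-vs-rest
problem).  Merging averages a subject's per-phase feature vectors, which
is legitimate because the design is balanced — every subject contributes
exactly one vector per phase.

The model family is the one typical of point-and-click discriminant
pipelines: linear discriminant analysis, linear- and Gaussian-kernel
max-margin classifiers, and a random-subspace ensemble of linear
discriminants (30 learners on ceil(p/2)-dimensional random feature
subsets).  Features are z-scored inside each training fold; model
selection uses stratified 10-fold cross-validated accuracy, the winner is
refitted on all training data and evaluated once on the held-out test
split (default 20 %, grouped by subject so no subject spans the split).

``PhaseClassifier`` is the model object; ``fit()`` returns a
``PhaseClassificationResults`` carrying validation/test accuracy, macro
one-vs-rest AUC, the confusion matrix with per-class TPR/FNR, the
per-model comparison and the ANOVA feature ranking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import accuracy_score, confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .protocol import PHASE_LABELS
from .ranking import rank_features

MODALITY_PREFIX = {"EEG": "EEG__", "EMG": "EMG__", "COP": "COP__"}


@dataclass(frozen=True)
class MergeConfig:
    """Mapping from output class name to the set of input phases it merges."""

    name: str
    groups: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        used = [p for _, phases in self.groups for p in phases]
        if len(used) != len(set(used)):
            raise ValueError(f"merge {self.name!r}: phases appear in several groups")
        for p in used:
            if p not in PHASE_LABELS:
                raise ValueError(f"merge {self.name!r}: unknown phase {p!r}")

    @property
    def used_phases(self) -> tuple[str, ...]:
        return tuple(p for _, phases in self.groups for p in phases)

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.groups)

    @property
    def n_classes(self) -> int:
        return len(self.groups)


MERGE_CONFIGS: dict[str, MergeConfig] = {
    "six_phase": MergeConfig("six_phase", tuple(
        (p, (p,)) for p in PHASE_LABELS)),
    "five_phase": MergeConfig("five_phase", tuple(
        (p, (p,)) for p in PHASE_LABELS if p != "BL")),
    "four_phase_movement": MergeConfig("four_phase_movement", (
        ("BL", ("BL",)), ("PRE", ("PRE",)),
        ("MOVEMENT", ("P25", "P50", "P75")), ("POST", ("POST",)))),
    "three_phase_movement": MergeConfig("three_phase_movement", (
        ("PRE", ("PRE",)), ("MOVEMENT", ("P25", "P50", "P75")),
        ("POST", ("POST",)))),
    "binary_bl": MergeConfig("binary_bl", (
        ("BL", ("BL",)), ("NOT_BL", ("PRE", "P25", "P50", "P75", "POST")))),
}


def assemble_table(features_by_phase: pd.DataFrame,
                   merge: MergeConfig | str,
                   modalities: Iterable[str] = ("EEG", "EMG", "COP")) -> pd.DataFrame:
    """Build the (subject, class) × features table for one configuration.

    ``features_by_phase`` is the long cohort table (columns subject_id,
    phase, features).  Merged classes get the arithmetic mean of their
    constituent phases' vectors; the modality filter keeps columns with the
    requested prefixes.  Requesting CoP together with a configuration that
    uses BL is an error — the CoP recording starts only after baseline.
    """
    if isinstance(merge, str):
        merge = MERGE_CONFIGS[merge]
    modalities = tuple(m.upper() for m in modalities)
    for m in modalities:
        if m not in MODALITY_PREFIX:
            raise ValueError(f"unknown modality {m!r}")
    if "COP" in modalities and "BL" in merge.used_phases:
        raise ValueError(
            f"merge {merge.name!r} uses BL but CoP recording starts only after BL"
        )
    prefixes = tuple(MODALITY_PREFIX[m] for m in modalities)
    feat_cols = [c for c in features_by_phase.columns if c.startswith(prefixes)]
    if not feat_cols:
        raise ValueError(f"no feature columns for modalities {modalities}")

    wide = features_by_phase.set_index(["subject_id", "phase"])[feat_cols]
    have = set(features_by_phase["phase"].unique())
    missing = [p for p in merge.used_phases if p not in have]
    if missing:
        raise ValueError(f"phases {missing} absent from the feature table")

    rows = []
    for cls, phases in merge.groups:
        sub = wide[wide.index.get_level_values("phase").isin(phases)]
        merged = sub.groupby(level="subject_id", sort=True).mean()
        n_phases = sub.groupby(level="subject_id").size()
        if (n_phases != len(phases)).any():
            bad = n_phases.index[n_phases != len(phases)].tolist()
            raise ValueError(f"subjects {bad} missing phases for class {cls!r}")
        merged.insert(0, "label", cls)
        rows.append(merged.reset_index())
    table = pd.concat(rows, ignore_index=True)
    if table[feat_cols].isna().any().any():
        bad = table[feat_cols].columns[table[feat_cols].isna().any()].tolist()
        raise ValueError(f"missing values after assembly in {bad[:5]}")
    return table


def split(table: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0,
          group_by_subject: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified train/test split.

    With ``group_by_subject`` every row of a subject lands on the same side
    (the design is balanced, so subject-level splitting is automatically
    stratified by class).
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    if group_by_subject:
        subjects = np.array(sorted(table["subject_id"].unique()))
        if subjects.size < 2:
            raise ValueError("need at least 2 subjects to split")
        n_test = max(1, round(test_fraction * subjects.size))
        test_subjects = set(rng.permutation(subjects)[:n_test])
        mask = table["subject_id"].isin(test_subjects)
    else:
        mask = np.zeros(len(table), dtype=bool)
        for _, idx in table.groupby("label").groups.items():
            idx = np.asarray(idx)
            n_test = max(1, round(test_fraction * idx.size))
            mask[rng.permutation(idx)[:n_test]] = True
        mask = pd.Series(mask, index=table.index)
    return table[~mask].reset_index(drop=True), table[mask].reset_index(drop=True)


def make_models(n_features: int, seed: int = 0) -> dict[str, Pipeline]:
    """The four-model family, each behind a fold-internal z-scoring step."""
    subspace = max(1, math.ceil(n_features / 2))
    models = {
        "linear_discriminant": LinearDiscriminantAnalysis(),
        "linear_svm": SVC(kernel="linear", random_state=seed),
        "gaussian_svm": SVC(kernel="rbf", gamma="scale", random_state=seed),
        "subspace_discriminant": BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=30, max_features=subspace,
            bootstrap=False, bootstrap_features=False, random_state=seed),
    }
    return {name: Pipeline([("scale", StandardScaler()), ("clf", est)])
            for name, est in models.items()}


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("subject_id", "label")]


def _class_scores(model, X: np.ndarray) -> np.ndarray:
    """Per-class decision scores (n × K), from probabilities or margins."""
    try:
        return model.predict_proba(X)
    except AttributeError:
        df = model.decision_function(X)
        return np.column_stack([-df, df]) if df.ndim == 1 else df


def _macro_auc(y_true: np.ndarray, scores: np.ndarray,
               classes: np.ndarray) -> float:
    """Macro-averaged one-vs-rest AUC from per-class scores."""
    aucs = [roc_auc_score(y_true == cls, scores[:, k])
            for k, cls in enumerate(classes) if (y_true == cls).any()
            and not (y_true == cls).all()]
    return float(np.mean(aucs))


def train_models(train: pd.DataFrame, cv_folds: int = 10, seed: int = 0,
                 models: dict[str, Pipeline] | None = None):
    """Cross-validate the model family; refit the best on all training data.

    Returns ``(per_model, best_name, best_fitted)`` where ``per_model`` is a
    DataFrame with mean CV accuracy (%) and macro one-vs-rest AUC per model.
    """
    feat_cols = _feature_columns(train)
    X = train[feat_cols].to_numpy(dtype=float)
    y = train["label"].to_numpy()
    classes = np.unique(y)
    models = models or make_models(X.shape[1], seed)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    records = {}
    for name, pipe in models.items():
        accs, aucs = [], []
        for tr_idx, va_idx in skf.split(X, y):
            fitted = clone(pipe).fit(X[tr_idx], y[tr_idx])
            pred = fitted.predict(X[va_idx])
            accs.append(accuracy_score(y[va_idx], pred))
            aucs.append(_macro_auc(y[va_idx], _class_scores(fitted, X[va_idx]),
                                   classes))
        records[name] = {"validation_accuracy": 100.0 * float(np.mean(accs)),
                         "auc_validation": float(np.mean(aucs))}
    per_model = pd.DataFrame(records).T
    best_name = per_model["validation_accuracy"].idxmax()
    best = clone(models[best_name]).fit(X, y)
    best.feature_names_ = feat_cols
    return per_model, best_name, best


def evaluate(model, test: pd.DataFrame) -> dict:
    """Held-out evaluation: accuracy %, macro AUC, confusion with TPR/FNR."""
    feat_cols = _feature_columns(test)
    expected = getattr(model, "feature_names_", None)
    if expected is not None and list(expected) != feat_cols:
        raise ValueError("feature-name mismatch between training and test tables")
    X = test[feat_cols].to_numpy(dtype=float)
    y = test["label"].to_numpy()
    pred = model.predict(X)
    classes = model.classes_
    conf = confusion_matrix(y, pred, labels=classes)
    with np.errstate(invalid="ignore"):
        tpr = 100.0 * np.diag(conf) / conf.sum(axis=1)
    return {
        "test_accuracy": 100.0 * float(accuracy_score(y, pred)),
        "auc_test": _macro_auc(y, _class_scores(model, X), np.asarray(classes)),
        "confusion": pd.DataFrame(conf, index=list(classes), columns=list(classes)),
        "tpr": pd.Series(tpr, index=list(classes), name="TPR_pct"),
        "fnr": pd.Series(100.0 - tpr, index=list(classes), name="FNR_pct"),
    }


@dataclass
class PhaseClassificationResults:
    """Fitted-model report for one (modality set, merge) configuration."""

    merge_name: str
    modalities: tuple[str, ...]
    model_name: str
    validation_accuracy: float
    test_accuracy: float
    auc_validation: float
    auc_test: float
    confusion: pd.DataFrame
    tpr: pd.Series
    fnr: pd.Series
    per_model: pd.DataFrame
    ranking: pd.DataFrame | None
    seed: int
    n_subjects: int
    n_features: int
    estimator: object = field(repr=False, default=None)

    @property
    def top_features(self) -> list[str]:
        if self.ranking is None:
            return []
        return list(self.ranking.index[:3])

    def summary(self) -> str:
        lines = [
            f"Phase classification — merge={self.merge_name}, "
            f"modalities={'+'.join(self.modalities)}",
            f"  subjects: {self.n_subjects}   features: {self.n_features}   "
            f"seed: {self.seed}",
            f"  best model: {self.model_name}",
            f"  validation accuracy: {self.validation_accuracy:5.1f} %   "
            f"AUC: {self.auc_validation:.2f}",
            f"  test accuracy:       {self.test_accuracy:5.1f} %   "
            f"AUC: {self.auc_test:.2f}",
            "  per-model validation:",
        ]
        for name, row in self.per_model.iterrows():
            lines.append(f"    {name:<22s} {row['validation_accuracy']:5.1f} %  "
                         f"AUC {row['auc_validation']:.2f}")
        if self.ranking is not None:
            lines.append("  top features (ANOVA F): " + ", ".join(self.top_features))
        lines.append("  confusion (rows = true class, TPR/FNR in %):")
        for cls in self.confusion.index:
            counts = " ".join(f"{v:4d}" for v in self.confusion.loc[cls])
            lines.append(f"    {cls:<9s} {counts}   TPR {self.tpr[cls]:5.1f}  "
                         f"FNR {self.fnr[cls]:5.1f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "merge": self.merge_name,
            "modalities": list(self.modalities),
            "model": self.model_name,
            "validation_accuracy": self.validation_accuracy,
            "test_accuracy": self.test_accuracy,
            "auc_validation": self.auc_validation,
            "auc_test": self.auc_test,
            "confusion": {str(k): [int(v) for v in row]
                          for k, row in self.confusion.iterrows()},
            "tpr_pct": {str(k): float(v) for k, v in self.tpr.items()},
            "fnr_pct": {str(k): float(v) for k, v in self.fnr.items()},
            "top_features": self.top_features,
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "n_features": self.n_features,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def plot_confusion(self, ax=None):
        """Row-normalized confusion-matrix heat map."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        norm = self.confusion.to_numpy(dtype=float)
        norm = norm / norm.sum(axis=1, keepdims=True)
        im = ax.imshow(norm, vmin=0, vmax=1, cmap="Blues")
        ax.set_xticks(range(len(self.confusion)), self.confusion.columns)
        ax.set_yticks(range(len(self.confusion)), self.confusion.index)
        ax.set_xlabel("predicted class")
        ax.set_ylabel("true class")
        for i in range(norm.shape[0]):
            for j in range(norm.shape[1]):
                ax.text(j, i, f"{100 * norm[i, j]:.0f}", ha="center", va="center",
                        color="black" if norm[i, j] < 0.6 else "white")
        ax.figure.colorbar(im, ax=ax, label="row fraction")
        return ax


class PhaseClassifier:
    """Model object: a feature table plus the training protocol.

    Build from an assembled (subject, class) table — or straight from a
    cohort of recordings with :meth:`from_cohort` — then ``fit(seed)`` to
    obtain a :class:`PhaseClassificationResults`.
    """

    def __init__(self, table: pd.DataFrame,
                 merge_name: str = "custom",
                 modalities: tuple[str, ...] = (),
                 test_fraction: float = 0.2,
                 cv_folds: int = 10,
                 group_by_subject: bool = True,
                 rank_boot: int = 0):
        if table[_feature_columns(table)].isna().any().any():
            raise ValueError("feature table contains missing values")
        self.table = table
        self.merge_name = merge_name
        self.modalities = tuple(modalities) or self._infer_modalities(table)
        self.test_fraction = test_fraction
        self.cv_folds = cv_folds
        self.group_by_subject = group_by_subject
        self.rank_boot = rank_boot

    @staticmethod
    def _infer_modalities(table: pd.DataFrame) -> tuple[str, ...]:
        return tuple(m for m, pre in MODALITY_PREFIX.items()
                     if any(c.startswith(pre) for c in table.columns))

    @classmethod
    def from_cohort(cls, recordings, merge: MergeConfig | str,
                    modalities: Iterable[str] = ("EEG", "EMG", "COP"),
                    **kwargs) -> "PhaseClassifier":
        from .pipeline import cohort_feature_table

        if isinstance(merge, str):
            merge = MERGE_CONFIGS[merge]
        modalities = tuple(m.upper() for m in modalities)
        long = cohort_feature_table(recordings, modalities)
        table = assemble_table(long, merge, modalities)
        return cls(table, merge_name=merge.name, modalities=modalities, **kwargs)

    def fit(self, seed: int = 0) -> PhaseClassificationResults:
        train, test = split(self.table, self.test_fraction, seed,
                            self.group_by_subject)
        ranking = rank_features(self.table, n_boot=self.rank_boot, seed=seed)
        per_model, best_name, best = train_models(train, self.cv_folds, seed)
        ev = evaluate(best, test)
        return PhaseClassificationResults(
            merge_name=self.merge_name,
            modalities=self.modalities,
            model_name=best_name,
            validation_accuracy=float(per_model.loc[best_name,
                                                    "validation_accuracy"]),
            test_accuracy=ev["test_accuracy"],
            auc_validation=float(per_model.loc[best_name, "auc_validation"]),
            auc_test=ev["auc_test"],
            confusion=ev["confusion"],
            tpr=ev["tpr"], fnr=ev["fnr"],
            per_model=per_model,
            ranking=ranking,
            seed=seed,
            n_subjects=self.table["subject_id"].nunique(),
            n_features=len(_feature_columns(self.table)),
            estimator=best,
        )


def run_configuration(recordings, merge: MergeConfig | str,
                      modalities: Iterable[str], seed: int = 0,
                      **kwargs) -> PhaseClassificationResults:
    """Full pipeline for one configuration: segment → extract → assemble →
    rank → split → train → evaluate."""
    model = PhaseClassifier.from_cohort(recordings, merge, modalities, **kwargs)
    return model.fit(seed)
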