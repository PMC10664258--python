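"""Random-forest prediction of replicate relationships from (R^2, NMI).

Every unordered pair of cohort samples is labelled with one of three
classes from the sample sheet: pairs within the same experiment are
``true_replicate``; pairs from different experiments on the same cell line
are ``same_cell_line_independent``; everything else is
``different_cell_line``. Features are the co-zeros-removed R^2 and NMI
between the pair's WFpkm tracks. The over-represented different-cell-line
class is down-sampled, and a 100-tree entropy-criterion forest is trained
and evaluated across ten stratified 60:40 train:test splits; per-split
impurity importances of the two features are compared with a paired
Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .binning import WfpkmTrack
from .errors import ValidationError
from .metrics import make_bivariate, normalized_mutual_information, r_squared

CLASS_NAMES = ("different_cell_line", "same_cell_line_independent", "true_replicate")

FEATURE_NAMES = ("r_squared", "nmi")

DEFAULT_MAJORITY_TARGET = 39


@dataclass
class ForestReport:
    classes: tuple[str, ...]
    accuracies: np.ndarray  # one per fold
    importances: np.ndarray  # folds x 2, columns ordered as FEATURE_NAMES
    confusions: list[np.ndarray]  # 3x3 per fold, rows = true class
    per_class: list[pd.DataFrame]  # precision/recall/f1/support per fold
    feature_names: tuple[str, ...] = FEATURE_NAMES


@dataclass(frozen=True)
class ImportanceComparison:
    mean_paired_difference: float  # nmi importance - r_squared importance
    p_value: float
    n_folds: int


def assign_pair_classes(sheet: pd.DataFrame) -> pd.DataFrame:
    """All unordered sample pairs with the three-way relationship class.

    ``sheet`` needs columns ``sample``, ``cell_line`` and ``experiment_id``.
    """
    for col in ("sample", "cell_line", "experiment_id"):
        if col not in sheet.columns:
            raise ValidationError(f"sample sheet missing column {col!r}")
    if sheet["sample"].duplicated().any():
        raise ValidationError("duplicate sample names in sheet")
    info = sheet.set_index("sample")[["cell_line", "experiment_id"]]
    rows = []
    for a, b in combinations(sheet["sample"], 2):
        if info.loc[a, "experiment_id"] == info.loc[b, "experiment_id"]:
            klass = "true_replicate"
        elif info.loc[a, "cell_line"] == info.loc[b, "cell_line"]:
            klass = "same_cell_line_independent"
        else:
            klass = "different_cell_line"
        rows.append((a, b, klass))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "klass"])


def build_pair_feature_table(
    sheet: pd.DataFrame,
    tracks: Mapping[str, WfpkmTrack] | None = None,
    features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per unordered pair: class plus (R^2, NMI) features.

    Features are computed from ``tracks`` with co-zeros removed, or merged
    from a precomputed ``features`` frame with columns
    (sample_a, sample_b, r_squared, nmi).
    """
    pairs = assign_pair_classes(sheet)
    if tracks is not None:
        missing = set(sheet["sample"]) - set(tracks)
        if missing:
            raise ValidationError(f"tracks missing for samples: {sorted(missing)}")
        r2s, nmis = [], []
        for a, b in zip(pairs["sample_a"], pairs["sample_b"]):
            pair = make_bivariate(tracks[a], tracks[b], drop_cozeros=True)
            r2s.append(r_squared(pair).value)
            nmis.append(normalized_mutual_information(pair).value)
        pairs["r_squared"] = r2s
        pairs["nmi"] = nmis
    elif features is not None:
        key = ["sample_a", "sample_b"]
        pairs = pairs.merge(features[key + ["r_squared", "nmi"]], on=key, how="left")
        if pairs[["r_squared", "nmi"]].isna().any().any():
            raise ValidationError("features missing for some pairs")
    else:
        raise ValidationError("provide either tracks or a precomputed features frame")
    return pairs


def balance_classes(
    rows: pd.DataFrame,
    majority_target: int = DEFAULT_MAJORITY_TARGET,
    seed: int | None = None,
) -> pd.DataFrame:
    """Down-sample the majority class to ``majority_target`` rows.

    Sampling is uniform without replacement; every other class is kept
    exactly. Raises when the target exceeds the majority class size.
    """
    counts = rows["klass"].value_counts()
    majority = counts.idxmax()
    if majority_target > counts[majority]:
        raise ValidationError(
            f"target {majority_target} exceeds majority class size {counts[majority]}"
        )
    rng = np.random.default_rng(seed)
    major_rows = rows[rows["klass"] == majority]
    kept_idx = rng.choice(major_rows.index.to_numpy(), size=majority_target, replace=False)
    kept = pd.concat([rows[rows["klass"] != majority], rows.loc[np.sort(kept_idx)]])
    return kept.sort_index().reset_index(drop=True)


def crossvalidate_forest(
    rows: pd.DataFrame,
    *,
    test_fraction: float = 0.4,
    folds: int = 10,
    trees: int = 100,
    criterion: str = "entropy",
    seed: int | None = None,
    mode: Literal["shuffle", "kfold"] = "shuffle",
) -> ForestReport:
    """Train/evaluate the forest across stratified splits.

    Default mode is ten stratified random 60:40 train:test splits; a
    classical stratified K-fold is available with ``mode='kfold'`` (which
    ignores ``test_fraction``). Per fold: fit ``trees`` entropy-criterion
    decision trees on the two features, evaluate on the held-out portion,
    and record the impurity-based feature importances (which sum to one).
    """
    for col in ("r_squared", "nmi", "klass"):
        if col not in rows.columns:
            raise ValidationError(f"feature table missing column {col!r}")
    X = rows[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = rows["klass"].to_numpy()
    classes = tuple(sorted(np.unique(y)))
    counts = rows["klass"].value_counts()
    rng = np.random.default_rng(seed)
    if mode == "shuffle":
        if counts.min() < 2:
            raise ValidationError("each class needs >= 2 members for a stratified split")
        splitter = StratifiedShuffleSplit(
            n_splits=folds, test_size=test_fraction, random_state=int(rng.integers(2**31))
        )
    elif mode == "kfold":
        if counts.min() < folds:
            raise ValidationError(f"each class needs >= {folds} members for {folds}-fold CV")
        splitter = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    accuracies, importances, confusions, per_class = [], [], [], []
    for train_idx, test_idx in splitter.split(X, y):
        forest = RandomForestClassifier(
            n_estimators=trees,
            criterion=criterion,
            random_state=int(rng.integers(2**31)),
        )
        forest.fit(X[train_idx], y[train_idx])
        pred = forest.predict(X[test_idx])
        accuracies.append(float((pred == y[test_idx]).mean()))
        importances.append(forest.feature_importances_)
        confusions.append(confusion_matrix(y[test_idx], pred, labels=list(classes)))
        prec, rec, f1, support = precision_recall_fscore_support(
            y[test_idx], pred, labels=list(classes), zero_division=0
        )
        per_class.append(
            pd.DataFrame(
                {"precision": prec, "recall": rec, "f1": f1, "support": support},
                index=list(classes),
            )
        )
    return ForestReport(
        classes=classes,
        accuracies=np.array(accuracies),
        importances=np.vstack(importances),
        confusions=confusions,
        per_class=per_class,
    )


def compare_feature_importance(report: ForestReport) -> ImportanceComparison:
    """Paired Wilcoxon signed-rank on per-fold (NMI - R^2) importances."""
    if len(report.accuracies) < 2:
        raise ValidationError("need at least 2 folds to compare importances")
    i_r2 = report.feature_names.index("r_squared")
    i_nmi = report.feature_names.index("nmi")
    diffs = report.importances[:, i_nmi] - report.importances[:, i_r2]
    if np.all(diffs == 0):
        p = 1.0
    else:
        p = float(sps.wilcoxon(diffs).pvalue)
    return ImportanceComparison(float(diffs.mean()), p, len(diffs))


def report_to_dict(report: ForestReport) -> dict:
    """JSON-serializable view of a ForestReport."""
    return {
        "classes": list(report.classes),
        "feature_names": list(report.feature_names),
        "accuracies": report.accuracies.tolist(),
        "importances": report.importances.tolist(),
        "confusion_matrices": [c.tolist() for c in report.confusions],
        "per_class": [df.reset_index(names="klass").to_dict("records") for df in report.per_class],
    }
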