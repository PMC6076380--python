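"""Small-signature gradient-boosted-tree classifiers with leakage-free CV.

Protocol: inside every training fold of a repeated stratified k-fold
cross-validation, features (miRNAs) are ranked by their one-way ANOVA
F-value between the two classes and the top-k are kept; a gradient-boosted
tree classifier with per-class weights proportional to the inverse class
frequencies is fitted and scored on the held-out fold. A grid over signature
size, number of leaves and number of trees is searched; the winning grid
point (by mean cross-validated AUC) is refit on the full data to name the
reported signature. Selecting features outside the folds would leak the test
labels and inflate the AUC — a regression test guards against that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.feature_selection import f_classif
from sklearn.metrics import accuracy_score, balanced_accuracy_score, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .exceptions import ConfigurationError, StructuralError
from .matrix import ExpressionMatrix

__all__ = [
    "ClassifierConfig",
    "ClassifierReport",
    "anova_f_select",
    "class_weights",
    "cross_validated_fit",
    "pairwise_group_classification",
]


@dataclass
class ClassifierConfig:
    """Search grid and validation protocol for signature classifiers."""

    n_repeats: int = 5
    n_folds: int = 5
    feature_grid: Sequence[int] = tuple(range(2, 14))
    leaves_grid: Sequence[int] = (7, 15, 31)
    trees_grid: Sequence[int] = (50, 100, 200)
    learning_rate: float = 0.1
    seed: int = 0
    class_weighting: str = "by-ratio"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        for name in ("feature_grid", "leaves_grid", "trees_grid"):
            if not len(getattr(self, name)):
                raise ConfigurationError(f"{name} must be non-empty")
        if self.class_weighting not in ("by-ratio", "none"):
            raise ConfigurationError("class_weighting must be 'by-ratio' or 'none'")


@dataclass
class ClassifierReport:
    """Cross-validation outcome of the best grid point.

    ``accuracy`` and ``auc`` are cross-validated means in percent; the
    ``signature`` is the feature set selected on the full data at the winning
    signature size.
    """

    signature: list[str]
    accuracy: float
    auc: float
    best_params: dict
    per_fold: pd.DataFrame
    grid: pd.DataFrame
    n1: int
    n2: int
    model: object = field(default=None, repr=False)


def _as_xy(mat, labels) -> tuple[pd.DataFrame, np.ndarray]:
    """Accept an ExpressionMatrix or a features x samples frame/array; return samples x features."""
    if isinstance(mat, ExpressionMatrix):
        mat.require_state("log2")
        x = mat.values.T
    else:
        x = pd.DataFrame(mat).T
    y = np.asarray(labels)
    if x.shape[0] != y.size:
        raise StructuralError("labels length does not match the number of samples")
    return x, y


def _rank_features(x: pd.DataFrame, y: np.ndarray) -> list[str]:
    """Feature ids sorted by descending ANOVA F; ties broken lexicographically."""
    with np.errstate(invalid="ignore", divide="ignore"):
        f_values, _ = f_classif(x.to_numpy(float), y)
    f_values = np.nan_to_num(f_values, nan=0.0, posinf=np.finfo(float).max)
    return [fid for _, fid in sorted(zip(-f_values, x.columns), key=lambda t: (t[0], t[1]))]


def anova_f_select(mat, labels, k: int) -> list[str]:
    """Top-k features by between-class ANOVA F-value."""
    x, y = _as_xy(mat, labels)
    if len(np.unique(y)) != 2:
        raise ConfigurationError("exactly two classes are required")
    if not 1 <= k <= x.shape[1]:
        raise ConfigurationError(f"k={k} outside [1, {x.shape[1]}]")
    return _rank_features(x, y)[:k]


def class_weights(n1: int, n2: int) -> dict[int, float]:
    """Weights inversely proportional to class frequencies: w_c = N / (2 n_c).

    The minority:majority weight ratio equals n_majority / n_minority, i.e.,
    the classes are weighted according to their ratio.
    """
    if n1 < 1 or n2 < 1:
        raise ConfigurationError("both classes need at least one sample")
    total = n1 + n2
    return {0: total / (2 * n1), 1: total / (2 * n2)}


def _make_model(leaves: int, trees: int, lr: float, weights, seed: int) -> LGBMClassifier:
    return LGBMClassifier(
        num_leaves=leaves,
        n_estimators=trees,
        learning_rate=lr,
        class_weight=weights,
        min_child_samples=5,
        random_state=seed,
        n_jobs=1,
        verbose=-1,
    )


def cross_validated_fit(mat, labels, config: ClassifierConfig | None = None) -> ClassifierReport:
    """Grid-searched, repeated stratified CV with in-fold feature selection.

    Labels: 0 = class 1 (e.g. no cancer), 1 = class 2 (developed cancer).
    Deterministic given ``config.seed``.
    """
    config = config or ClassifierConfig()
    x, y = _as_xy(mat, labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ConfigurationError("exactly two classes are required")
    y01 = (y == classes[1]).astype(int)
    n1 = int((y01 == 0).sum())
    n2 = int((y01 == 1).sum())
    if min(n1, n2) < config.n_folds:
        raise ConfigurationError(
            f"minority class ({min(n1, n2)}) smaller than n_folds={config.n_folds}: "
            "stratified folds would lose a class"
        )
    max_k = max(config.feature_grid)
    if max_k > x.shape[1]:
        raise ConfigurationError(f"feature grid asks for {max_k} of {x.shape[1]} features")
    weights = class_weights(n1, n2) if config.class_weighting == "by-ratio" else None

    rskf = RepeatedStratifiedKFold(
        n_splits=config.n_folds, n_repeats=config.n_repeats, random_state=config.seed % 2**31
    )
    splits = list(rskf.split(x, y01))
    # rank features once per fold; every k reuses the prefix
    fold_rankings = [
        _rank_features(x.iloc[train], y01[train])[:max_k] for train, _ in splits
    ]

    records = []
    for k in config.feature_grid:
        for leaves in config.leaves_grid:
            for trees in config.trees_grid:
                for fold_idx, (train, test) in enumerate(splits):
                    feats = fold_rankings[fold_idx][:k]
                    model = _make_model(
                        leaves, trees, config.learning_rate, weights, config.seed % 2**31
                    )
                    model.fit(x.iloc[train][feats], y01[train])
                    proba = model.predict_proba(x.iloc[test][feats])[:, 1]
                    records.append(
                        {
                            "k": k,
                            "num_leaves": leaves,
                            "n_estimators": trees,
                            "fold": fold_idx,
                            "auc": roc_auc_score(y01[test], proba),
                            "accuracy": accuracy_score(y01[test], (proba >= 0.5).astype(int)),
                            "balanced_accuracy": balanced_accuracy_score(
                                y01[test], (proba >= 0.5).astype(int)
                            ),
                        }
                    )
    per_fold = pd.DataFrame(records)
    grid = (
        per_fold.groupby(["k", "num_leaves", "n_estimators"])[["auc", "accuracy"]]
        .mean()
        .reset_index()
    )
    # best by mean AUC; parsimony tie-break (fewer features, then smaller model)
    grid = grid.sort_values(
        ["auc", "k", "num_leaves", "n_estimators"], ascending=[False, True, True, True]
    ).reset_index(drop=True)
    best = grid.iloc[0]
    best_params = {
        "k": int(best["k"]),
        "num_leaves": int(best["num_leaves"]),
        "n_estimators": int(best["n_estimators"]),
    }
    signature = _rank_features(x, y01)[: best_params["k"]]
    final = _make_model(
        best_params["num_leaves"],
        best_params["n_estimators"],
        config.learning_rate,
        weights,
        config.seed % 2**31,
    )
    final.fit(x[signature], y01)
    return ClassifierReport(
        signature=list(signature),
        accuracy=float(best["accuracy"] * 100),
        auc=float(best["auc"] * 100),
        best_params=best_params,
        per_fold=per_fold,
        grid=grid,
        n1=n1,
        n2=n2,
        model=final,
    )


def pairwise_group_classification(
    mat: ExpressionMatrix,
    ann: pd.DataFrame,
    pairs: Sequence[tuple[int, int]],
    config: ClassifierConfig | None = None,
) -> tuple[pd.DataFrame, dict[tuple[int, int], ClassifierReport]]:
    """Run the CV protocol for each requested pair of history/outcome groups.

    Returns a summary table (one row per pair) and the full reports.
    """
    config = config or ClassifierConfig()
    group = ann.set_index("sample_id")["group"].astype(int).reindex(mat.values.columns)
    known = set(group.dropna().unique())
    reports: dict[tuple[int, int], ClassifierReport] = {}
    rows = []
    for ga, gb in pairs:
        if ga not in known or gb not in known:
            raise ConfigurationError(f"unknown group label in pair ({ga}, {gb})")
        ids = group.index[group.isin([ga, gb])].tolist()
        sub = mat.subset_samples(ids)
        labels = (group.loc[ids] == gb).astype(int).to_numpy()
        report = cross_validated_fit(sub, labels, config)
        reports[(ga, gb)] = report
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "n_a": report.n1,
                "n_b": report.n2,
                "k": report.best_params["k"],
                "num_leaves": report.best_params["num_leaves"],
                "n_estimators": report.best_params["n_estimators"],
                "accuracy_pct": report.accuracy,
                "auc_pct": report.auc,
                "signature": ",".join(report.signature),
            }
        )
    return pd.DataFrame(rows), reports
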