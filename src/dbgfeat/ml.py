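"""Random Forest classification and PCA on coverage feature tables.

A trained model is bound to an ordered feature list, its category order,
and its seed; prediction validates feature compatibility and realigns
rows rather than trusting incoming order.  Cross-validation is stratified
whenever the fold count permits and falls back to plain seeded K-fold
otherwise (small balanced designs often want more folds than the class
size allows); ``stratified="require"`` restores a strict error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef
from sklearn.model_selection import KFold, StratifiedKFold

from . import __version__
from .features import FeatureTable
from .selection import GroupLabels

__all__ = ["TrainedModel", "fit", "cross_validate", "predict", "pca", "PCAResult"]

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 100


@dataclass
class TrainedModel:
    classifier: RandomForestClassifier
    feature_ids: list[str]
    categories: list[str]
    n_trees: int
    seed: int
    k: int | None = None

    def save(self, path: str | Path) -> None:
        """Binary model artifact plus an embedded JSON sidecar."""
        path = Path(path)
        joblib.dump(self, path)
        sidecar = {
            "feature_ids": self.feature_ids,
            "categories": self.categories,
            "k": self.k,
            "n_trees": self.n_trees,
            "seed": self.seed,
            "tool_version": __version__,
        }
        with open(path.with_suffix(path.suffix + ".json"), "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise ValueError(f"{path} is not a model artifact")
        return model


def _xy(table: FeatureTable, labels: GroupLabels):
    unlabelled = [s for s in table.sample_ids if s not in labels.assignment]
    if unlabelled:
        raise ValueError(f"unlabelled samples in table: {', '.join(unlabelled)}")
    X = table.values.T.to_numpy(dtype=np.float64)  # samples x features
    y = np.array([labels.assignment[s] for s in table.sample_ids])
    return X, y


def fit(
    table: FeatureTable,
    labels: GroupLabels,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    k: int | None = None,
) -> TrainedModel:
    """Fit a Random Forest (default 100 trees) on a feature table."""
    X, y = _xy(table, labels)
    present = sorted(set(y))
    if len(present) < 2:
        raise ValueError(f"training data contains a single class: {present}")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(X, y)
    train_acc = accuracy_score(y, clf.predict(X))
    logger.info("fit: %d samples, %d features, training accuracy %.3f", *X.shape, train_acc)
    return TrainedModel(
        classifier=clf,
        feature_ids=table.feature_ids,
        categories=list(clf.classes_),
        n_trees=n_trees,
        seed=seed,
        k=k,
    )


def cross_validate(
    table: FeatureTable,
    labels: GroupLabels,
    folds: int = 10,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    stratified: str = "auto",
) -> dict:
    """Seeded k-fold CV with accuracy, macro-F1 and MCC per fold and pooled.

    Uses stratified folds when folds <= smallest class size; with
    ``stratified="auto"`` larger fold counts fall back to plain shuffled
    K-fold (folds > n_samples is always an error), with ``"require"``
    they raise.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X, y = _xy(table, labels)
    if len(set(y)) < 2:
        raise ValueError("cross-validation needs >= 2 classes")
    if folds > len(y):
        raise ValueError(f"folds={folds} exceeds the number of samples ({len(y)})")
    smallest = min(np.unique(y, return_counts=True)[1])
    if folds <= smallest:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    elif stratified == "auto":
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        raise ValueError(
            f"stratified {folds}-fold impossible with smallest class of {smallest} samples"
        )
    per_fold = {"accuracy": [], "f1_macro": [], "mcc": []}
    y_true_all, y_pred_all = [], []
    for train_idx, test_idx in splitter.split(X, y):
        if len(set(y[train_idx])) < 2:
            raise ValueError("a training fold contains a single class; reduce folds")
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        per_fold["accuracy"].append(float(accuracy_score(y[test_idx], pred)))
        per_fold["f1_macro"].append(
            float(f1_score(y[test_idx], pred, average="macro", zero_division=0))
        )
        per_fold["mcc"].append(_safe_mcc(y[test_idx], pred))
        y_true_all.extend(y[test_idx])
        y_pred_all.extend(pred)
    result = {
        "folds": folds,
        "per_fold": per_fold,
        "mean": {m: float(np.mean(v)) for m, v in per_fold.items()},
        "pooled": {
            "accuracy": float(accuracy_score(y_true_all, y_pred_all)),
            "f1_macro": float(f1_score(y_true_all, y_pred_all, average="macro", zero_division=0)),
            "mcc": _safe_mcc(np.array(y_true_all), np.array(y_pred_all)),
        },
    }
    return result


def _safe_mcc(y_true, y_pred) -> float:
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        return float(matthews_corrcoef(y_true, y_pred))


def predict(model: TrainedModel, table: FeatureTable) -> dict[str, tuple[str, dict[str, float]]]:
    """Classify each sample; probabilities ordered by the model's categories.

    The table's features must be a superset of the model's; rows are
    realigned, never silently reordered or imputed.
    """
    missing = [f for f in model.feature_ids if f not in set(table.feature_ids)]
    if missing:
        raise ValueError(f"feature table lacks model features: {', '.join(missing[:10])}")
    aligned = table.values.loc[model.feature_ids]
    X = aligned.T.to_numpy(dtype=np.float64)
    labels = model.classifier.predict(X)
    proba = model.classifier.predict_proba(X)
    class_order = list(model.classifier.classes_)
    out: dict[str, tuple[str, dict[str, float]]] = {}
    for i, sid in enumerate(table.sample_ids):
        probs = {c: float(proba[i, class_order.index(c)]) for c in model.categories}
        out[sid] = (str(labels[i]), probs)
    return out


def write_predictions_tsv(
    predictions: dict[str, tuple[str, dict[str, float]]], categories: list[str], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tpredicted_label\t" + "\t".join(categories) + "\n")
        for sid, (label, probs) in predictions.items():
            cols = "\t".join(f"{probs[c]:.6f}" for c in categories)
            fh.write(f"{sid}\t{label}\t{cols}\n")


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray

    def __getitem__(self, sample_id: str) -> np.ndarray:
        return self.coordinates.loc[sample_id].to_numpy()


def pca(table: FeatureTable, n_components: int = 2) -> PCAResult:
    """Project samples (observations) onto principal components.

    Deterministic up to sign; the sign is fixed by forcing each
    component's largest-magnitude feature loading to be positive.
    """
    X = table.values.T.to_numpy(dtype=np.float64)  # samples x features
    if n_components > min(X.shape):
        raise ValueError(f"n_components={n_components} exceeds min(N, M)={min(X.shape)}")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("feature table has zero variance; PCA undefined")
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(X)
    for j in range(n_components):
        load = model.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
            model.components_[j] *= -1
    df = pd.DataFrame(
        coords, index=table.sample_ids, columns=[f"PC{j+1}" for j in range(n_components)]
    )
    return PCAResult(coordinates=df, explained_variance_ratio=model.explained_variance_ratio_)
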