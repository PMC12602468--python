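"""Disease-stage classification from flattened directed-connectivity features.

Each subject's N x N connectivity matrix (continuous TPDC values by
default, or the thresholded binary matrix) is flattened row-major into a
feature vector whose columns are named "SRC->TGT" (source channel ->
target channel, matching the matrix convention entry (target, source)).
A random forest (default 100 trees) is trained on a stratified 70:30
split, evaluated with accuracy / per-class precision / recall / F1 / ROC,
cross-validated with stratified k-fold, and its impurity importances are
ranked to report the top discriminating connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.utils.validation import check_is_fitted

from .datatypes import MatrixRecord


def feature_names(
    channels: tuple[str, ...], include_diagonal: bool = True
) -> list[str]:
    """Row-major flattening order: for each target row i, each source column j."""
    names = []
    for i, tgt in enumerate(channels):
        for j, src in enumerate(channels):
            if include_diagonal or i != j:
                names.append(f"{src}->{tgt}")
    return names


@dataclass
class FeatureTable:
    """Subjects x connection-features with per-subject stage labels."""

    features: pd.DataFrame  # index = subject ids, columns = "SRC->TGT"
    labels: pd.Series  # aligned stage label per subject
    channels: tuple[str, ...]
    mode: str = "tpdc"
    include_diagonal: bool = True

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share the subject index")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        if self.labels.nunique() < 2:
            raise ValueError("need at least 2 classes")

    @property
    def x(self) -> np.ndarray:
        return self.features.to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy()


def build_features(
    matrices: list[MatrixRecord],
    labels: dict[str, str] | list[str],
    mode: str = "tpdc",
    include_diagonal: bool = True,
) -> FeatureTable:
    """Flatten per-subject connectivity matrices into a feature table.

    ``mode`` selects which matrix kind is expected ('tpdc' continuous
    values or 'binary'). Labels are given either per subject id (dict) or
    positionally.
    """
    if mode not in ("tpdc", "binary"):
        raise ValueError(f"mode must be 'tpdc' or 'binary', got {mode!r}")
    if not matrices:
        raise ValueError("no matrices supplied")
    channels = matrices[0].channels
    rows, ids, labs = [], [], []
    for k, rec in enumerate(matrices):
        if rec.channels != channels:
            raise ValueError(
                f"channel mismatch for subject {rec.subject_id!r}: "
                f"{rec.channels} vs {channels}"
            )
        if rec.kind != mode:
            raise ValueError(
                f"subject {rec.subject_id!r} matrix kind {rec.kind!r} != mode {mode!r}"
            )
        vals = rec.values
        mask = (
            np.ones(vals.shape, bool) if include_diagonal else ~np.eye(len(channels), dtype=bool)
        )
        rows.append(vals[mask])
        sid = rec.subject_id or f"subject_{k}"
        ids.append(sid)
        labs.append(labels[sid] if isinstance(labels, dict) else labels[k])
    frame = pd.DataFrame(
        rows, index=ids, columns=feature_names(channels, include_diagonal)
    )
    return FeatureTable(
        features=frame,
        labels=pd.Series(labs, index=ids, name="stage"),
        channels=channels,
        mode=mode,
        include_diagonal=include_diagonal,
    )


class StageClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest disease-stage classifier over connectivity features.

    Thin scikit-learn estimator around RandomForestClassifier with the
    pipeline's defaults (100 trees); forest hyperparameters beyond the tree
    count stay at library defaults and are recorded in reports.
    """

    def __init__(self, n_trees: int = 100, random_state: int = 0):
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y):
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state
        )
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.feature_importances_ = self.forest_.feature_importances_
        self.n_features_in_ = self.forest_.n_features_in_
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(X)


@dataclass
class ClassifierReport:
    """Evaluation summary of one train/test run plus cross-validation."""

    accuracy: float
    per_class: dict[str, dict[str, float]]  # precision / recall / f1 / support
    confusion: np.ndarray
    class_order: list[str]
    roc_auc: float | None
    roc_points: tuple[np.ndarray, np.ndarray] | None
    cv_mean: float | None
    cv_sd: float | None
    top_features: list[tuple[str, float]]
    n_train: int
    n_test: int
    seed: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "confusion_matrix": self.confusion.tolist(),
            "class_order": self.class_order,
            "roc_auc": self.roc_auc,
            "cv_mean": self.cv_mean,
            "cv_sd": self.cv_sd,
            "top_features": [[n, float(v)] for n, v in self.top_features],
            "n_train": self.n_train,
            "n_test": self.n_test,
            "seed": self.seed,
            "params": self.params,
        }


def rank_features(
    model: StageClassifier | RandomForestClassifier,
    names: list[str],
    k: int = 5,
) -> list[tuple[str, float]]:
    """Top-k features by impurity importance, descending."""
    imps = (
        model.feature_importances_
        if hasattr(model, "feature_importances_")
        else model.forest_.feature_importances_
    )
    order = np.argsort(imps)[::-1][:k]
    return [(names[i], float(imps[i])) for i in order]


def train_eval(
    table: FeatureTable,
    n_trees: int = 100,
    test_fraction: float = 0.30,
    seed: int = 0,
    positive_class: str | None = None,
    cv_folds: int | None = None,
    top_k: int = 5,
) -> ClassifierReport:
    """Stratified split, forest fit, held-out metrics, optional CV and ROC.

    The positive class for the ROC curve defaults to the lexicographically
    first label (override with ``positive_class``, e.g. the prodromal
    stage). Deterministic given the seed.
    """
    x, y = table.x, table.y
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 10:
        raise ValueError(
            f"need >= 10 subjects per class for a stable stratified split; "
            f"smallest class has {counts.min()}"
        )
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    clf = StageClassifier(n_trees=n_trees, random_state=seed).fit(x_tr, y_tr)
    y_hat = clf.predict(x_te)
    acc = float(accuracy_score(y_te, y_hat))
    prec, rec, f1, supp = precision_recall_fscore_support(
        y_te, y_hat, labels=classes, zero_division=0
    )
    per_class = {
        str(c): {
            "precision": float(p),
            "recall": float(r),
            "f1": float(f),
            "support": int(s),
        }
        for c, p, r, f, s in zip(classes, prec, rec, f1, supp)
    }
    conf = confusion_matrix(y_te, y_hat, labels=classes)

    roc_auc = None
    roc_points = None
    if len(classes) == 2:
        pos = positive_class or str(classes[0])
        pos_idx = list(clf.classes_).index(pos)
        score = clf.predict_proba(x_te)[:, pos_idx]
        y_bin = (y_te == pos).astype(int)
        roc_auc = float(roc_auc_score(y_bin, score))
        fpr, tpr, _ = roc_curve(y_bin, score)
        roc_points = (fpr, tpr)

    cv_mean = cv_sd = None
    if cv_folds:
        cv_mean, cv_sd = cross_validate(
            table, n_folds=cv_folds, n_trees=n_trees, seed=seed
        )

    names = list(table.features.columns)
    return ClassifierReport(
        accuracy=acc,
        per_class=per_class,
        confusion=conf,
        class_order=[str(c) for c in classes],
        roc_auc=roc_auc,
        roc_points=roc_points,
        cv_mean=cv_mean,
        cv_sd=cv_sd,
        top_features=rank_features(clf, names, k=top_k),
        n_train=len(y_tr),
        n_test=len(y_te),
        seed=seed,
        params=clf.forest_.get_params(),
    )


def cross_validate(
    table: FeatureTable, n_folds: int = 10, n_trees: int = 100, seed: int = 0
) -> tuple[float, float]:
    """Stratified k-fold accuracy (mean, sd) of the forest on the full table."""
    _, counts = np.unique(table.y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"cannot stratify {n_folds} folds: smallest class has {counts.min()}"
        )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(
        StageClassifier(n_trees=n_trees, random_state=seed),
        table.x,
        table.y,
        cv=cv,
        scoring="accuracy",
    )
    return float(scores.mean()), float(scores.std())
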