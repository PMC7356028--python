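"""Random-forest classification of residue pairs.

Feature stacks and label sets are flattened into per-pair training tables,
the majority (negative) class is down-sampled to a fixed ratio, and a
random forest is fitted after an F1-scored hyperparameter grid search on a
stratified 75:25 split. Evaluation reports the confusion matrix together
with accuracy, ROC AUC, macro and weighted precision/recall/F1,
specificity and MCC; leave-one-complex-out cross-validation trains one
model per held-out complex and scores it on that complex's full,
un-sampled pair grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    confusion_matrix,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, train_test_split

from .features import ALL_FEATURES, FeatureStack
from .labeling import PairLabelSet

#: Hyperparameter grid searched by default (an artifact choice; override freely).
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [100, 300, 500],
    "max_depth": [None, 10, 20],
    "max_features": ["sqrt", 0.3],
    "min_samples_leaf": [1, 5],
}

#: Small grid for quick runs and tests.
FAST_GRID: dict[str, list] = {
    "n_estimators": [100],
    "max_depth": [None, 10],
    "max_features": ["sqrt"],
    "min_samples_leaf": [1],
}

META_COLUMNS = ("complex_id", "i", "j")


def assemble_table(
    complex_id: str,
    stack: FeatureStack,
    labels: PairLabelSet,
    feature_order: Sequence[str] = ALL_FEATURES,
) -> pd.DataFrame:
    """Flatten one complex's stack + labels into a per-pair table.

    Columns: complex_id, i, j (1-based), the features in canonical order,
    and the binary label.
    """
    m, n = stack.shape
    if (labels.M, labels.N) != (m, n):
        raise ValueError(
            f"label grid ({labels.M}, {labels.N}) does not match stack shape {(m, n)}"
        )
    missing = [f for f in feature_order if f not in stack]
    if missing:
        raise ValueError(f"stack is missing feature(s): {missing}")
    ii, jj = np.meshgrid(np.arange(1, m + 1), np.arange(1, n + 1), indexing="ij")
    data = {
        "complex_id": complex_id,
        "i": ii.ravel(),
        "j": jj.ravel(),
    }
    for f in feature_order:
        data[f] = stack[f].ravel()
    data["label"] = labels.as_matrix().ravel()
    df = pd.DataFrame(data)
    if df.isna().any().any():
        raise ValueError("training table contains missing values")
    return df


def downsample_majority(
    table: pd.DataFrame, ratio: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Keep all positives; sample negatives to ``ratio`` x positives.

    Sampling is uniform without replacement and deterministic under
    ``seed``; if fewer negatives than the quota exist, all are kept.
    """
    pos = table[table["label"] == 1]
    neg = table[table["label"] == 0]
    if len(pos) == 0:
        raise ValueError("training table has no positive rows")
    quota = ratio * len(pos)
    if len(neg) > quota:
        neg = neg.sample(n=quota, replace=False, random_state=seed)
    out = pd.concat([pos, neg]).sort_index()
    return out.reset_index(drop=True)


@dataclass
class TrainedModel:
    """Fitted forest plus every piece of preprocessing state needed at inference."""

    forest: RandomForestClassifier
    hyperparameters: dict[str, Any]
    feature_order: tuple[str, ...]
    kernel_spec: dict[str, Any] | None = None
    ssp_ranks: dict[str, int] | None = None
    scaling_mode: str = "per-complex"
    sampling_ratio: int = 5
    seed: int = 0
    training_complexes: tuple[str, ...] = ()
    holdout_f1: float | None = None

    def metadata(self) -> dict[str, Any]:
        return {
            "hyperparameters": self.hyperparameters,
            "feature_order": list(self.feature_order),
            "kernel_spec": self.kernel_spec,
            "ssp_ranks": self.ssp_ranks,
            "scaling_mode": self.scaling_mode,
            "sampling_ratio": self.sampling_ratio,
            "seed": self.seed,
            "training_complexes": list(self.training_complexes),
            "holdout_f1": self.holdout_f1,
        }

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} does not hold a TrainedModel")
        return model


def grid_search_fit(
    table: pd.DataFrame,
    grid: Mapping[str, list] | None = None,
    seed: int = 0,
    *,
    feature_order: Sequence[str] = ALL_FEATURES,
    cv: int = 3,
    test_fraction: float = 0.25,
    kernel_spec: dict | None = None,
    ssp_ranks: dict | None = None,
    sampling_ratio: int = 5,
) -> TrainedModel:
    """Grid-search a random forest on a stratified 75:25 split.

    The grid point maximizing cross-validated F1 on the 75% training split
    is refitted on that split; the held-out 25% F1 is stored on the model
    for reporting.
    """
    grid = dict(grid) if grid is not None else DEFAULT_GRID
    y = table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")
    x = table[list(feature_order)].to_numpy()
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed, n_jobs=1),
        param_grid=grid,
        scoring="f1",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(x_tr, y_tr)
    forest: RandomForestClassifier = search.best_estimator_
    holdout_f1 = float(f1_score(y_te, forest.predict(x_te), zero_division=0))
    return TrainedModel(
        forest=forest,
        hyperparameters=dict(search.best_params_),
        feature_order=tuple(feature_order),
        kernel_spec=kernel_spec,
        ssp_ranks=ssp_ranks,
        sampling_ratio=sampling_ratio,
        seed=seed,
        training_complexes=tuple(sorted(set(table["complex_id"]))),
        holdout_f1=holdout_f1,
    )


def predict_matrix(
    model: TrainedModel, stack: FeatureStack, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair interface probabilities and their thresholded binary matrix."""
    missing = [f for f in model.feature_order if f not in stack]
    if missing:
        raise ValueError(f"stack is missing model feature(s): {missing}")
    m, n = stack.shape
    x = np.column_stack([stack[f].ravel() for f in model.feature_order])
    positive_col = list(model.forest.classes_).index(1)
    prob = model.forest.predict_proba(x)[:, positive_col].reshape(m, n)
    return prob, (prob > threshold).astype(int)


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix and derived rates for one evaluated pair grid."""

    tn: int
    fp: int
    fn: int
    tp: int
    accuracy: float
    auc: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    specificity: float
    mcc: float

    @property
    def n_pairs(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def evaluate(
    binary: np.ndarray,
    labels: PairLabelSet,
    prob: np.ndarray | None = None,
) -> EvalReport:
    """Score a binary prediction matrix against a label set.

    ``prob`` supplies scores for the ROC AUC; without it the binary matrix
    is used. AUC is NaN when only one class is present in the labels.
    """
    y_true = labels.as_matrix().ravel()
    y_pred = np.asarray(binary).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction and label shapes disagree")
    if y_true.size == 0:
        raise ValueError("empty label set")
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    scores = np.asarray(prob).ravel() if prob is not None else y_pred
    auc = (
        float(roc_auc_score(y_true, scores))
        if len(np.unique(y_true)) == 2
        else float("nan")
    )
    specificity = tn / (tn + fp) if tn + fp else 0.0
    return EvalReport(
        tn=int(tn),
        fp=int(fp),
        fn=int(fn),
        tp=int(tp),
        accuracy=float((tp + tn) / y_true.size),
        auc=auc,
        precision_macro=float(
            precision_score(y_true, y_pred, average="macro", zero_division=0)
        ),
        recall_macro=float(
            recall_score(y_true, y_pred, average="macro", zero_division=0)
        ),
        f1_macro=float(f1_score(y_true, y_pred, average="macro", zero_division=0)),
        precision_weighted=float(
            precision_score(y_true, y_pred, average="weighted", zero_division=0)
        ),
        recall_weighted=float(
            recall_score(y_true, y_pred, average="weighted", zero_division=0)
        ),
        f1_weighted=float(
            f1_score(y_true, y_pred, average="weighted", zero_division=0)
        ),
        specificity=float(specificity),
        mcc=float(matthews_corrcoef(y_true, y_pred)),
    )


def leave_one_out(
    complexes: Sequence[tuple[str, FeatureStack, PairLabelSet]],
    *,
    ratio: int = 5,
    seed: int = 0,
    grid: Mapping[str, list] | None = None,
    feature_order: Sequence[str] = ALL_FEATURES,
    cv: int = 3,
    return_models: bool = False,
) -> dict[str, EvalReport] | dict[str, tuple[TrainedModel, EvalReport]]:
    """Leave-one-complex-out cross-validation.

    For each complex: train (with down-sampling) on all other complexes,
    then evaluate on the held-out complex's complete pair grid. With
    ``return_models`` each value is ``(model, report)``.
    """
    ids = [cid for cid, _, _ in complexes]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate complex ids")
    if len(ids) < 2:
        raise ValueError("leave-one-out needs at least 2 complexes")
    reports: dict = {}
    for held_id, held_stack, held_labels in complexes:
        train = pd.concat(
            [
                assemble_table(cid, stack, labels, feature_order)
                for cid, stack, labels in complexes
                if cid != held_id
            ],
            ignore_index=True,
        )
        train = downsample_majority(train, ratio=ratio, seed=seed)
        model = grid_search_fit(
            train,
            grid=grid,
            seed=seed,
            feature_order=feature_order,
            cv=cv,
            sampling_ratio=ratio,
        )
        prob, binary = predict_matrix(model, held_stack)
        report = evaluate(binary, held_labels, prob=prob)
        reports[held_id] = (model, report) if return_models else report
    return reports


def feature_importance(model: TrainedModel) -> list[tuple[str, float]]:
    """Impurity-based importances (non-negative, sum 1), sorted descending."""
    try:
        imp = model.forest.feature_importances_
    except AttributeError as exc:  # not fitted
        raise ValueError("model is not fitted") from exc
    ranked = sorted(zip(model.feature_order, imp), key=lambda t: -t[1])
    return [(name, float(v)) for name, v in ranked]
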