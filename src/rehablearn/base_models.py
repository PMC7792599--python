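"""Base classifiers: gradient-boosted trees (xgboost) and k-NN, with
grid-search tuning, probabilistic prediction, per-class centroids in
normalized feature space, feature importances and incremental updates.

Both models are trained on the same stratified 80/20 split with
five-fold cross-validated grid search; the boosted model uses a softmax
multiclass objective (its native binary objective for two classes) with
an initial maximum depth of twice the class count.  Incremental updates
append the new labelled record to the k-NN store in O(1), warm-start the
boosted model with a few extra boosting rounds (existing trees are kept)
and update the affected class centroid as a running mean.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    train_test_split,
)

from .errors import (
    StateError,
    StratificationError,
    TaxonomyError,
    ValidationError,
)
from .schema_io import FEATURE_COLUMNS, LabelTaxonomy, RehabDataset, SubjectRecord

logger = logging.getLogger(__name__)

#: boosting rounds added per incremental update (bounded per-session cost)
WARM_START_ROUNDS = 5


def default_boosted_grid(n_classes: int) -> dict[str, list]:
    """Compact default tuning grid (8 points)."""
    return {
        "learning_rate": [0.1, 0.3],
        "n_estimators": [50, 100],
        "max_depth": [3, 2 * n_classes],
    }


def full_boosted_grid(n_classes: int) -> dict[str, list]:
    """The wide reference grid over every tunable named in the design."""
    return {
        "learning_rate": [0.05, 0.1, 0.3],
        "n_estimators": [50, 100, 200],
        "max_depth": [3, 2 * n_classes, 4 * n_classes],
        "subsample": [0.8, 1.0],
        "colsample_bytree": [0.8, 1.0],
        "reg_alpha": [0.0, 1.0],
        "reg_lambda": [0.0, 1.0],
    }


@dataclass
class BoostedModelSpec:
    """Configuration of the boosted-tree model and its tuning grid.

    ``max_depth_initial`` defaults to 2 × the number of classes — the
    multi-class starting point — and the grid (None → compact default)
    is searched by mean fold accuracy.
    """

    grid: dict[str, list] | None = None
    max_depth_initial: int | None = None
    seed: int = 0

    def resolve_grid(self, n_classes: int) -> dict[str, list]:
        grid = self.grid if self.grid is not None else default_boosted_grid(n_classes)
        if not grid or any(len(v) == 0 for v in grid.values()):
            raise ValidationError("boosted tuning grid must be non-empty")
        return grid


@dataclass
class KnnModelSpec:
    """k-NN configuration: initial k = 5, Euclidean distance on
    normalized features, k tuned over a small grid."""

    k: int = 5
    k_grid: tuple[int, ...] = (1, 3, 5, 7, 9)

    def __post_init__(self):
        if self.k < 1 or any(k < 1 for k in self.k_grid):
            raise ValidationError("k must be >= 1")


class KnnModel:
    """Exact brute-force k-NN with vote-fraction probabilities.

    Stores its training set in appendable arrays so an incremental
    insertion is O(1); queries scan all stored points (exact Euclidean
    distances, stable tie-handling: equal distances keep insertion
    order, equal votes go to the lowest class code).
    """

    def __init__(self, k: int, n_classes: int):
        self.k = k
        self.n_classes = n_classes
        self._X: list[np.ndarray] = []
        self._y: list[int] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KnnModel":
        self._X = [np.asarray(row, dtype=float) for row in X]
        self._y = [int(v) for v in y]
        if self.k > len(self._y):
            raise ValidationError(f"k={self.k} exceeds training size {len(self._y)}")
        return self

    def append(self, x: np.ndarray, label: int) -> None:
        self._X.append(np.asarray(x, dtype=float))
        self._y.append(int(label))

    @property
    def n_samples(self) -> int:
        return len(self._y)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        X = np.vstack(self._X)
        d = np.sqrt(((X - np.asarray(x, dtype=float)) ** 2).sum(axis=1))
        k = min(self.k, len(d))
        order = np.argsort(d, kind="stable")[:k]
        probs = np.zeros(self.n_classes)
        for idx in order:
            probs[self._y[idx]] += 1.0
        return probs / k

    def predict(self, x: np.ndarray) -> int:
        return int(np.argmax(self.predict_proba(x)))


class _SklearnKnnAdapter(BaseEstimator, ClassifierMixin):
    """Thin sklearn-estimator facade over KnnModel for GridSearchCV."""

    def __init__(self, k: int = 5, n_classes: int = 2):
        self.k = k
        self.n_classes = n_classes

    def fit(self, X, y):
        self.classes_ = np.arange(self.n_classes)
        self.model_ = KnnModel(min(self.k, len(y)), self.n_classes).fit(X, y)
        return self

    def predict(self, X):
        return np.array([self.model_.predict(x) for x in np.asarray(X)])

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def _make_xgb(n_classes: int, seed: int, max_depth: int, **overrides) -> xgb.XGBClassifier:
    params = dict(
        max_depth=max_depth,
        n_estimators=100,
        learning_rate=0.3,
        n_jobs=1,
        random_state=seed,
        verbosity=0,
        tree_method="exact",
    )
    if n_classes > 2:
        params["objective"] = "multi:softprob"
        params["num_class"] = n_classes
    params.update(overrides)
    return xgb.XGBClassifier(**params)


class BoostedModel:
    """A trained gradient-boosted forest with cheap in-place warm starts.

    Wraps the native booster directly so an incremental update adds
    boosting rounds without serializing or copying the existing trees
    (the sklearn estimator round-trips the whole model per fit, which
    grows per-session cost with model size).
    """

    def __init__(
        self,
        booster: xgb.Booster,
        n_classes: int,
        n_rounds: int,
        class_codes: np.ndarray | None = None,
    ):
        self.booster = booster
        self.n_classes = n_classes  # taxonomy size (probability vector length)
        self.n_rounds = n_rounds
        # taxonomy codes the booster was trained on, ascending; the booster
        # works in the compressed 0..len(class_codes)-1 label space
        self.class_codes = (
            np.arange(n_classes) if class_codes is None else np.asarray(class_codes)
        )
        self.feature_importances_raw: dict[str, float] = {}

    @classmethod
    def from_sklearn(cls, clf: xgb.XGBClassifier, n_classes: int,
                     class_codes: np.ndarray) -> "BoostedModel":
        booster = clf.get_booster().copy()
        model = cls(booster, n_classes, booster.num_boosted_rounds(), class_codes)
        imp = np.asarray(clf.feature_importances_, dtype=float)
        model.feature_importances_raw = {
            col: float(v) for col, v in zip(FEATURE_COLUMNS, imp)
        }
        return model

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        raw = self.booster.inplace_predict(X)
        if raw.ndim == 1:  # binary objective: probability of class 1
            raw = np.column_stack([1.0 - raw, raw])
        out = np.zeros((len(raw), self.n_classes))
        out[:, self.class_codes] = raw
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def encode_labels(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=int)
        enc = np.searchsorted(self.class_codes, y)
        bad = (enc >= len(self.class_codes)) | (self.class_codes[
            np.clip(enc, 0, len(self.class_codes) - 1)
        ] != y)
        if bad.any():
            raise TaxonomyError(
                f"label(s) {sorted(set(y[bad].tolist()))} not among the classes "
                f"this boosted model was trained on"
            )
        return enc

    def boost_rounds(self, X: np.ndarray, y: np.ndarray, rounds: int) -> None:
        """Fit `rounds` extra trees on (X, y), keeping existing trees."""
        dtrain = xgb.DMatrix(
            np.asarray(X, dtype=float), label=self.encode_labels(y)
        )
        for _ in range(rounds):
            self.booster.update(dtrain, iteration=self.n_rounds)
            self.n_rounds += 1


@dataclass
class ModelPair:
    """Trained boosted + k-NN models for one label axis, with the fitted
    preprocessing parameters and per-class centroids they assume."""

    axis: str
    taxonomy: LabelTaxonomy
    boosted: BoostedModel
    knn: KnnModel
    normalization: object  # preprocess.NormalizationParams
    centroids: dict[int, np.ndarray]
    class_counts: dict[int, int]
    feature_importances: dict[str, float]
    training_log: dict = field(default_factory=dict)
    _train_X: np.ndarray | None = None
    _train_y: np.ndarray | None = None

    def clone(self) -> "ModelPair":
        return copy.deepcopy(self)

    def normalize_record(self, record: SubjectRecord) -> np.ndarray:
        vec = np.asarray(record.feature_vector(), dtype=float)
        return np.array(
            [
                self.normalization.transform_column(col, vec[i])
                for i, col in enumerate(FEATURE_COLUMNS)
            ]
        ).ravel()


def _features_and_labels(dataset: RehabDataset, axis: str):
    X = dataset.frame[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = dataset.labels(axis).to_numpy(dtype=int)
    return X, y


def class_centroids(dataset: RehabDataset, axis: str) -> dict[int, np.ndarray]:
    """Per-class arithmetic mean of the records' feature vectors.

    Requires a normalized dataset (centroids feed Euclidean distances).
    """
    if dataset.normalization is None:
        raise StateError("centroids are defined in normalized feature space")
    X, y = _features_and_labels(dataset, axis)
    out: dict[int, np.ndarray] = {}
    for code in np.unique(y):
        out[int(code)] = X[y == code].mean(axis=0)
    if not out:
        raise ValidationError("no records to form centroids from")
    return out


def _importances(model: BoostedModel) -> dict[str, float]:
    imp = np.array(
        [model.feature_importances_raw.get(col, 0.0) for col in FEATURE_COLUMNS]
    )
    if imp.sum() <= 0:
        imp = np.full(len(FEATURE_COLUMNS), 1.0 / len(FEATURE_COLUMNS))
    else:
        imp = imp / imp.sum()
    return {col: float(v) for col, v in zip(FEATURE_COLUMNS, imp)}


def tune_and_train(
    dataset: RehabDataset,
    axis: str,
    boosted_spec: BoostedModelSpec | None = None,
    knn_spec: KnnModelSpec | None = None,
    folds: int = 5,
    split: float = 0.8,
    seed: int = 0,
) -> tuple[ModelPair, dict]:
    """Grid-search both base models with stratified k-fold CV.

    The data are split 80/20 stratified; hyperparameters are chosen by
    mean fold accuracy on the training split and the final models are
    refit on the full training split.  Returns (pair, cv_report); the
    report carries chosen parameters, per-fold and mean accuracies, and
    the train/test row indices of the split.
    """
    if dataset.normalization is None:
        raise StateError("train on normalized data (fit_normalizer/apply_normalizer)")
    boosted_spec = boosted_spec or BoostedModelSpec(seed=seed)
    knn_spec = knn_spec or KnnModelSpec()
    taxonomy = dataset.taxonomies[axis]
    n_classes = taxonomy.n_classes
    X, y = _features_and_labels(dataset, axis)

    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=split, stratify=y, random_state=seed
    )
    y_tr = y[train_idx]
    counts = np.bincount(y_tr, minlength=n_classes)
    present = counts[np.unique(y_tr)]
    if present.min() < folds:
        raise StratificationError(
            f"every class needs >= {folds} training records for {folds}-fold "
            f"stratified CV; smallest has {int(present.min())}"
        )
    X_tr = X[train_idx]
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    # the booster works in a compressed 0..k-1 label space over the classes
    # actually present in training; predictions scatter back to taxonomy codes
    obs_codes = np.unique(y_tr)
    y_enc = np.searchsorted(obs_codes, y_tr)
    depth0 = boosted_spec.max_depth_initial or 2 * n_classes
    xgb_search = GridSearchCV(
        _make_xgb(len(obs_codes), boosted_spec.seed, depth0),
        boosted_spec.resolve_grid(n_classes),
        cv=cv,
        scoring="accuracy",
        n_jobs=1,
        refit=True,
    )
    xgb_search.fit(X_tr, y_enc)

    max_k = int(min(max(knn_spec.k_grid), np.floor(len(y_tr) * (folds - 1) / folds)))
    k_grid = [k for k in knn_spec.k_grid if k <= max_k] or [1]
    knn_search = GridSearchCV(
        _SklearnKnnAdapter(n_classes=n_classes),
        {"k": k_grid},
        cv=cv,
        scoring="accuracy",
        n_jobs=1,
        refit=False,
    )
    knn_search.fit(X_tr, y_tr)
    best_k = int(knn_search.best_params_["k"])
    knn = KnnModel(best_k, n_classes).fit(X_tr, y_tr)

    train_ds = dataset.replace_frame(dataset.frame.iloc[train_idx])
    centroids = class_centroids(train_ds, axis)
    class_counts = {int(c): int(n) for c, n in zip(*np.unique(y_tr, return_counts=True))}

    def _fold_scores(search):
        i = search.best_index_
        return [
            float(search.cv_results_[f"split{f}_test_score"][i]) for f in range(folds)
        ]

    cv_report = {
        "boosted": {
            "params": dict(xgb_search.best_params_),
            "fold_accuracies": _fold_scores(xgb_search),
            "mean_accuracy": float(xgb_search.best_score_),
        },
        "knn": {
            "params": {"k": best_k},
            "fold_accuracies": _fold_scores(knn_search),
            "mean_accuracy": float(knn_search.best_score_),
        },
        "train_indices": train_idx.tolist(),
        "test_indices": test_idx.tolist(),
    }
    boosted = BoostedModel.from_sklearn(
        xgb_search.best_estimator_, n_classes, obs_codes
    )
    pair = ModelPair(
        axis=axis,
        taxonomy=taxonomy,
        boosted=boosted,
        knn=knn,
        normalization=dataset.normalization,
        centroids=centroids,
        class_counts=class_counts,
        feature_importances=_importances(boosted),
        training_log=cv_report,
        _train_X=X_tr.copy(),
        _train_y=y_tr.copy(),
    )
    return pair, cv_report


# new sessions may fall somewhat outside the training [-1, 1] box; raw
# (unnormalized) records have features orders of magnitude larger, so a
# loose bound still catches the use-before-normalize mistake
_NORM_TOL = 3.0


def _check_normalized(x: np.ndarray) -> None:
    if np.any(np.abs(x) > _NORM_TOL):
        raise StateError(
            "record does not look normalized; use ModelPair.normalize_record first"
        )


def predict_with_probs(
    pair: ModelPair, record: SubjectRecord | np.ndarray
) -> dict[str, tuple[int, np.ndarray]]:
    """Both models' (class, probability vector) for one normalized record.

    Probability vectors are non-negative and sum to 1; the returned class
    is the argmax with ties broken toward the lowest class code.
    """
    x = (
        pair.normalize_record(record)
        if isinstance(record, SubjectRecord)
        else np.asarray(record, dtype=float)
    )
    _check_normalized(x)
    xgb_probs = pair.boosted.predict_proba(x.reshape(1, -1))[0]
    knn_probs = pair.knn.predict_proba(x)
    return {
        "xgb": (int(np.argmax(xgb_probs)), xgb_probs),
        "knn": (int(np.argmax(knn_probs)), knn_probs),
    }


def incremental_update(
    pair: ModelPair, record: SubjectRecord | np.ndarray, label: int
) -> ModelPair:
    """Fold one labelled record into both models (in place).

    k-NN gains the point in O(1).  The boosted model is warm-started:
    WARM_START_ROUNDS extra trees are fitted on the appended training
    set continuing from the existing booster.  The labelled class's
    centroid is updated as a running mean.
    """
    label = int(label)
    if not 0 <= label < pair.taxonomy.n_classes:
        raise TaxonomyError(f"label code {label} outside taxonomy {pair.axis!r}")
    x = (
        pair.normalize_record(record)
        if isinstance(record, SubjectRecord)
        else np.asarray(record, dtype=float)
    )
    pair.knn.append(x, label)

    pair._train_X = np.vstack([pair._train_X, x[None, :]])
    pair._train_y = np.append(pair._train_y, label)
    pair.boosted.boost_rounds(pair._train_X, pair._train_y, WARM_START_ROUNDS)

    n = pair.class_counts.get(label, 0)
    if label in pair.centroids:
        pair.centroids[label] = (pair.centroids[label] * n + x) / (n + 1)
    else:
        pair.centroids[label] = x.copy()
    pair.class_counts[label] = n + 1
    return pair


def save_model_pair(pair: ModelPair, directory: str | Path) -> None:
    """Serialize a ModelPair to a directory of text artifacts."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pair.boosted.booster.save_model(directory / "boosted.json")
    store = {
        "axis": pair.axis,
        "test_type": pair.taxonomy.test_type,
        "n_rounds": pair.boosted.n_rounds,
        "class_codes": pair.boosted.class_codes.tolist(),
        "k": pair.knn.k,
        "n_classes": pair.knn.n_classes,
        "knn_X": [list(map(float, row)) for row in pair.knn._X],
        "knn_y": pair.knn._y,
        "train_X": pair._train_X.tolist(),
        "train_y": pair._train_y.tolist(),
        "centroids": {str(c): v.tolist() for c, v in pair.centroids.items()},
        "class_counts": {str(c): n for c, n in pair.class_counts.items()},
        "normalization": {k: list(v) for k, v in pair.normalization.ranges.items()},
        "feature_importances": pair.feature_importances,
        "training_log": pair.training_log,
    }
    with open(directory / "pair.json", "w", encoding="utf-8") as fh:
        json.dump(store, fh)


def load_model_pair(directory: str | Path) -> ModelPair:
    from .preprocess import NormalizationParams
    from .schema_io import TAXONOMIES

    directory = Path(directory)
    with open(directory / "pair.json", encoding="utf-8") as fh:
        store = json.load(fh)
    taxonomy = TAXONOMIES[(store["test_type"], store["axis"])]
    booster = xgb.Booster()
    booster.load_model(directory / "boosted.json")
    boosted = BoostedModel(
        booster,
        store["n_classes"],
        store["n_rounds"],
        np.asarray(store["class_codes"], dtype=int),
    )
    boosted.feature_importances_raw = dict(store["feature_importances"])
    knn = KnnModel(store["k"], store["n_classes"])
    knn._X = [np.asarray(r, dtype=float) for r in store["knn_X"]]
    knn._y = [int(v) for v in store["knn_y"]]
    return ModelPair(
        axis=store["axis"],
        taxonomy=taxonomy,
        boosted=boosted,
        knn=knn,
        normalization=NormalizationParams(
            {k: tuple(v) for k, v in store["normalization"].items()}
        ),
        centroids={int(c): np.asarray(v) for c, v in store["centroids"].items()},
        class_counts={int(c): n for c, n in store["class_counts"].items()},
        feature_importances=store["feature_importances"],
        training_log=store["training_log"],
        _train_X=np.asarray(store["train_X"], dtype=float),
        _train_y=np.asarray(store["train_y"], dtype=int),
    )
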