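"""Base classifiers over feature vectors and whole-sequence models.

Four base learners are provided behind a common interface (fit /
ranking_score / predict): an unweighted sum, the classic log-odds model, a
support vector machine and a random forest. ``CREClassifier`` composes a
motif scanner, a feature-space specification and one of these learners into
a whole-sequence estimator; the CPREdictor (log-odds over motif-pair
frequencies) and Dummy PREdictor (its unweighted counterpart) are presets.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureSpace, SequenceFeaturizer
from .seqdata import LabelledSequence

ARCHIVE_FORMAT = "pymocca-model-v1"

__all__ = [
    "LogOddsClassifier",
    "UnweightedSumModel",
    "MulticlassSVM",
    "MulticlassRF",
    "ConstantPositiveClassifier",
    "CREClassifier",
    "cpredictor",
    "dummy_predictor",
    "fit_logodds",
    "fit_svm",
    "fit_rf",
    "score_dummy",
    "save_model",
    "load_model",
]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def _resolve_positive(classes: np.ndarray, positive_label) -> object:
    if positive_label is not None:
        if positive_label not in classes:
            raise ValueError(f"positive label {positive_label!r} not among classes {list(classes)}")
        return positive_label
    # default: lexicographically last class (documented convention)
    return classes[-1]


class LogOddsClassifier(BaseEstimator, ClassifierMixin):
    """Two-class log-odds model over nonnegative frequency features.

    Each feature f gets weight w(f) = ln((mean_pos(f) + p) / (mean_neg(f) + p))
    where the means are class means of the (per-kilobase) feature values and
    p > 0 is an additive pseudocount guaranteeing finite weights. The score of
    a vector is the weighted sum of its values.
    """

    def __init__(self, pseudocount: float = 0.1, positive_label=None):
        self.pseudocount = pseudocount
        self.positive_label = positive_label

    def fit(self, X, y) -> "LogOddsClassifier":
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        X = _as_frame(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"log-odds model requires exactly 2 classes, got {len(classes)}")
        pos = _resolve_positive(classes, self.positive_label)
        neg = classes[classes != pos][0]
        mean_pos = X[y == pos].mean(axis=0)
        mean_neg = X[y == neg].mean(axis=0)
        # computed as a difference of logs so that swapping the classes
        # negates every weight bit-exactly
        self.weights_ = np.log(mean_pos + self.pseudocount) - np.log(
            mean_neg + self.pseudocount
        )
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.classes_ = np.array([neg, pos], dtype=object)
        return self

    def decision_function(self, X) -> np.ndarray:
        X = _as_frame(X)
        if list(X.columns) != list(self.feature_names_in_):
            X = X.reindex(columns=self.feature_names_in_, fill_value=0.0)
        return np.asarray(X @ self.weights_.values, dtype=float)

    def ranking_score(self, X, positive_label=None) -> np.ndarray:
        return self.decision_function(X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


class UnweightedSumModel(BaseEstimator, ClassifierMixin):
    """Scores a feature vector by the plain sum of its values."""

    def __init__(self, positive_label=None):
        self.positive_label = positive_label

    def fit(self, X, y=None) -> "UnweightedSumModel":
        X = _as_frame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        if y is not None:
            self.classes_ = np.unique(np.asarray(y))
        return self

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(_as_frame(X).sum(axis=1), dtype=float)

    def ranking_score(self, X, positive_label=None) -> np.ndarray:
        return self.decision_function(X)

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return np.where(d > 0, self.classes_[-1], self.classes_[0])


def score_dummy(x) -> float:
    """Unweighted sum of a single feature vector."""
    return float(np.asarray(x, dtype=float).sum())


_KERNELS = {
    "linear": dict(kernel="linear"),
    "quadratic": dict(kernel="poly", degree=2, coef0=1.0, gamma="scale"),
    "rbf": dict(kernel="rbf", gamma="scale"),
}


def _check_not_degenerate(X: pd.DataFrame) -> None:
    variances = X.var(axis=0, ddof=0)
    if (variances == 0).all():
        const = ", ".join(map(str, X.columns[: 8]))
        raise ValueError(f"degenerate training set: all features constant ({const}...)")


class MulticlassSVM(BaseEstimator, ClassifierMixin):
    """SVM over standardized features; multi-class via one-vs-one voting.

    The ranking score for CRE prediction is the signed distance to the
    boundary (binary) or the one-vs-rest-aggregated margin of the positive
    class minus the best competing class (multi-class).
    """

    def __init__(
        self,
        kernel: str = "quadratic",
        C: float = 1.0,
        class_weight="balanced",
        random_state: int = 0,
    ):
        self.kernel = kernel
        self.C = C
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y) -> "MulticlassSVM":
        X = _as_frame(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("SVM requires at least 2 classes")
        _check_not_degenerate(X)
        if self.kernel not in _KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.scaler_ = StandardScaler().fit(X.values)
        self.svc_ = SVC(
            C=self.C,
            class_weight=self.class_weight,
            decision_function_shape="ovr",
            random_state=self.random_state,
            **_KERNELS[self.kernel],
        ).fit(self.scaler_.transform(X.values), y)
        self.classes_ = self.svc_.classes_
        return self

    def decision_function(self, X) -> np.ndarray:
        X = _as_frame(X)
        return self.svc_.decision_function(self.scaler_.transform(X.values))

    def ranking_score(self, X, positive_label=None) -> np.ndarray:
        pos = _resolve_positive(self.classes_, positive_label)
        d = self.decision_function(X)
        if len(self.classes_) == 2:
            return d if pos == self.classes_[1] else -d
        i = int(np.flatnonzero(self.classes_ == pos)[0])
        others = np.delete(d, i, axis=1)
        return d[:, i] - others.max(axis=1)

    def predict(self, X) -> np.ndarray:
        X = _as_frame(X)
        return self.svc_.predict(self.scaler_.transform(X.values))


class MulticlassRF(BaseEstimator, ClassifierMixin):
    """Random forest; ranking score is the positive-class vote fraction."""

    def __init__(
        self,
        n_trees: int = 300,
        max_depth: int | None = None,
        max_features="sqrt",
        class_weight=None,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.max_features = max_features
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y) -> "MulticlassRF":
        if self.n_trees < 1:
            raise ValueError("number of trees must be >= 1")
        X = _as_frame(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("random forest requires at least 2 classes")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.rf_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            max_features=self.max_features,
            class_weight=self.class_weight,
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X.values, y)
        self.classes_ = self.rf_.classes_
        return self

    def predict_proba(self, X) -> np.ndarray:
        return self.rf_.predict_proba(_as_frame(X).values)

    def ranking_score(self, X, positive_label=None) -> np.ndarray:
        pos = _resolve_positive(self.classes_, positive_label)
        i = int(np.flatnonzero(self.classes_ == pos)[0])
        return self.predict_proba(X)[:, i]

    def decision_function(self, X) -> np.ndarray:
        return self.ranking_score(X)

    def predict(self, X) -> np.ndarray:
        return self.rf_.predict(_as_frame(X).values)


class ConstantPositiveClassifier(BaseEstimator, ClassifierMixin):
    """Classifies every instance as the positive class (diagnostic baseline)."""

    def __init__(self, positive_label="positive"):
        self.positive_label = positive_label

    def fit(self, X=None, y=None) -> "ConstantPositiveClassifier":
        self.classes_ = np.array([self.positive_label], dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        n = len(X)
        return np.full(n, self.positive_label, dtype=object)

    def ranking_score(self, X, positive_label=None) -> np.ndarray:
        return np.ones(len(X))


def _make_base(base: str, *, pseudocount, positive_label, kernel, C, n_trees,
               max_depth, random_state):
    if base == "logodds":
        return LogOddsClassifier(pseudocount=pseudocount, positive_label=positive_label)
    if base == "sum":
        return UnweightedSumModel(positive_label=positive_label)
    if base == "svm":
        return MulticlassSVM(kernel=kernel, C=C, random_state=random_state)
    if base == "rf":
        return MulticlassRF(n_trees=n_trees, max_depth=max_depth, random_state=random_state)
    raise ValueError(f"unknown base model {base!r}")


class CREClassifier(BaseEstimator, ClassifierMixin):
    """Whole-sequence CRE model: motif scan -> feature spaces -> base learner.

    ``decision_function`` returns the ranking score used for precision/recall
    evaluation and thresholding: the log-odds or unweighted-sum score, the
    SVM margin of the positive class, or the RF positive-class vote fraction.
    """

    def __init__(
        self,
        motifs: Sequence = (),
        spaces: Sequence[FeatureSpace] = (FeatureSpace("motif-frequency"),),
        base: str = "logodds",
        positive_label=None,
        pseudocount: float = 0.1,
        kernel: str = "quadratic",
        C: float = 1.0,
        n_trees: int = 300,
        max_depth: int | None = None,
        both_strands: bool = True,
        random_state: int = 0,
    ):
        self.motifs = motifs
        self.spaces = spaces
        self.base = base
        self.positive_label = positive_label
        self.pseudocount = pseudocount
        self.kernel = kernel
        self.C = C
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.both_strands = both_strands
        self.random_state = random_state

    def _labels(self, X, y) -> np.ndarray:
        if y is not None:
            return np.asarray(y)
        return np.asarray([s.label for s in X])

    def fit(self, X: Sequence[LabelledSequence], y=None) -> "CREClassifier":
        y = self._labels(X, y)
        self.featurizer_ = SequenceFeaturizer(
            motifs=self.motifs, spaces=self.spaces, both_strands=self.both_strands
        ).fit()
        F = self.featurizer_.transform(X)
        self.model_ = _make_base(
            self.base,
            pseudocount=self.pseudocount,
            positive_label=self.positive_label,
            kernel=self.kernel,
            C=self.C,
            n_trees=self.n_trees,
            max_depth=self.max_depth,
            random_state=self.random_state,
        ).fit(F, y)
        self.classes_ = getattr(self.model_, "classes_", np.unique(y))
        self.positive_label_ = _resolve_positive(self.classes_, self.positive_label)
        return self

    def decision_function(self, X: Sequence[LabelledSequence]) -> np.ndarray:
        F = self.featurizer_.transform(X)
        return self.model_.ranking_score(F, self.positive_label_)

    def predict(self, X: Sequence[LabelledSequence]) -> np.ndarray:
        F = self.featurizer_.transform(X)
        return self.model_.predict(F)


def cpredictor(
    motifs: Sequence,
    pair_cutoff: int = 219,
    pseudocount: float = 0.1,
    positive_label=None,
    **kwargs,
) -> CREClassifier:
    """The CPREdictor: log-odds over motif-pair occurrence frequencies."""
    return CREClassifier(
        motifs=motifs,
        spaces=(FeatureSpace("motif-pair-frequency", pair_cutoff=pair_cutoff),),
        base="logodds",
        pseudocount=pseudocount,
        positive_label=positive_label,
        **kwargs,
    )


def dummy_predictor(motifs: Sequence, pair_cutoff: int = 219, **kwargs) -> CREClassifier:
    """The Dummy PREdictor: unweighted sum of motif-pair frequencies."""
    return CREClassifier(
        motifs=motifs,
        spaces=(FeatureSpace("motif-pair-frequency", pair_cutoff=pair_cutoff),),
        base="sum",
        **kwargs,
    )


# thin functional wrappers over the estimators -------------------------------


def fit_logodds(X, y, pseudocount: float = 0.1, positive_label=None) -> LogOddsClassifier:
    return LogOddsClassifier(pseudocount, positive_label).fit(X, y)


def fit_svm(X, y, kernel: str = "quadratic", C: float = 1.0, class_weight="balanced",
            seed: int = 0) -> MulticlassSVM:
    return MulticlassSVM(kernel, C, class_weight, seed).fit(X, y)


def fit_rf(X, y, trees: int = 300, max_depth: int | None = None,
           max_features="sqrt", seed: int = 0) -> MulticlassRF:
    return MulticlassRF(trees, max_depth, max_features, None, seed).fit(X, y)


# persistence ----------------------------------------------------------------


def save_model(model, path) -> None:
    """Persist any fitted pymocca model to a single versioned archive."""
    joblib.dump({"format": ARCHIVE_FORMAT, "model": model}, path, compress=3)


def load_model(path):
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != ARCHIVE_FORMAT:
        raise ValueError(f"{path}: not a {ARCHIVE_FORMAT} archive")
    return payload["model"]
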