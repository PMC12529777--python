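"""Model-dependent split hardness: train once, evaluate ID and OOD.

A pluggable :class:`ModelAdapter` is fit on the training set (model choices
may consult the ID-validation set only), then scored on the ID test set and
the OOD test set with ROC-AUC, accuracy, and the top-N hit rate. The ID −
OOD difference of a metric is the performance gap; positive gaps mean
degradation under distribution shift.

Adapters ship for the three classical model families (random forest, linear
SVM, gradient boosting) on ECFP4 fingerprints, each with fixed
hyperparameters; anything honoring the same contract (``fit`` /
``predict_scores`` with scores in [0, 1]) plugs in, which is the extension
point for graph neural networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy.special import expit
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

from .chem import MoleculeRecord, ecfp_matrix
from .workflow import DatasetSplit

__all__ = [
    "ModelAdapter",
    "SklearnAdapter",
    "EvalResult",
    "make_adapter",
    "default_model_pool",
    "roc_auc",
    "top_n_hit_rate",
    "accuracy",
    "train_and_evaluate",
    "performance_gap",
]


class ModelAdapter(Protocol):
    """Contract every evaluated model honors."""

    name: str

    def fit(self, features: np.ndarray, labels: np.ndarray) -> None: ...

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        """Activity scores in [0, 1], higher = more likely active."""
        ...


class SklearnAdapter:
    """Wrap an sklearn-style estimator as a :class:`ModelAdapter`.

    Estimators exposing ``predict_proba`` use the positive-class
    probability; margin-based estimators (e.g. linear SVMs) map their
    decision function through a sigmoid, which preserves ranking and keeps
    the 0.5 accuracy threshold at the decision boundary.
    """

    def __init__(self, estimator, name: str):
        self.estimator = estimator
        self.name = name
        self._fitted = False

    def fit(self, features: np.ndarray, labels: np.ndarray) -> None:
        self.estimator.fit(features, labels)
        self._fitted = True

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("fit must be called before predict_scores")
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(features)[:, 1]
        return expit(self.estimator.decision_function(features))


#: Fixed hyperparameters per adapter; no per-split tuning.
_ADAPTER_FACTORIES = {
    "rf": lambda seed: RandomForestClassifier(
        n_estimators=300, max_features="sqrt", n_jobs=1, random_state=seed
    ),
    "svm": lambda seed: LinearSVC(C=1.0, max_iter=5000, random_state=seed),
    "xgb": lambda seed: XGBClassifier(
        n_estimators=300,
        max_depth=6,
        learning_rate=0.1,
        eval_metric="logloss",
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    ),
}


def make_adapter(name: str, seed: int = 0) -> SklearnAdapter:
    """One of the reference classical adapters: ``rf``, ``svm``, ``xgb``."""
    try:
        factory = _ADAPTER_FACTORIES[name]
    except KeyError:
        raise ValueError(
            f"unknown adapter {name!r}; choose from {sorted(_ADAPTER_FACTORIES)}"
        ) from None
    return SklearnAdapter(factory(seed), name)


def default_model_pool(seed: int = 0) -> list[SklearnAdapter]:
    """A pool of classical model variants (fixed hyperparameters each) for
    ID-vs-OOD correlation studies, spanning weak to strong learners."""
    return [
        SklearnAdapter(
            RandomForestClassifier(n_estimators=300, n_jobs=1, random_state=seed),
            "rf",
        ),
        SklearnAdapter(
            RandomForestClassifier(
                n_estimators=50, max_depth=6, n_jobs=1, random_state=seed
            ),
            "rf-shallow",
        ),
        SklearnAdapter(
            XGBClassifier(
                n_estimators=300, max_depth=6, learning_rate=0.1,
                eval_metric="logloss", random_state=seed, n_jobs=1, verbosity=0,
            ),
            "xgb",
        ),
        SklearnAdapter(
            XGBClassifier(
                n_estimators=60, max_depth=2, learning_rate=0.3,
                eval_metric="logloss", random_state=seed, n_jobs=1, verbosity=0,
            ),
            "xgb-shallow",
        ),
        SklearnAdapter(
            LinearSVC(C=1.0, max_iter=5000, random_state=seed), "svm-linear"
        ),
        SklearnAdapter(
            LogisticRegression(C=1.0, max_iter=2000, random_state=seed), "logreg"
        ),
        SklearnAdapter(
            ExtraTreesClassifier(n_estimators=300, n_jobs=1, random_state=seed),
            "extratrees",
        ),
        SklearnAdapter(KNeighborsClassifier(n_neighbors=15), "knn"),
    ]


@dataclass
class EvalResult:
    """Metrics of one trained model on the ID and OOD test sets."""

    model_name: str
    roc_auc_id: float
    roc_auc_ood: float
    accuracy_id: float
    accuracy_ood: float
    hit_rate_ood: float
    top_n_tp: int
    top_n_fp: int
    provenance: dict = field(default_factory=dict)

    @property
    def gap_auc(self) -> float:
        return self.roc_auc_id - self.roc_auc_ood

    @property
    def gap_acc(self) -> float:
        return self.accuracy_id - self.accuracy_ood

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "roc_auc_id": self.roc_auc_id,
            "roc_auc_ood": self.roc_auc_ood,
            "gap_auc": self.gap_auc,
            "accuracy_id": self.accuracy_id,
            "accuracy_ood": self.accuracy_ood,
            "gap_acc": self.gap_acc,
            "hit_rate_ood": self.hit_rate_ood,
            "top_n_tp": self.top_n_tp,
            "top_n_fp": self.top_n_fp,
            "provenance": self.provenance,
        }


# ---------------------------------------------------------------------------
# metrics


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Probability that a random active outranks a random inactive, ties
    counting one half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores)))


def accuracy(labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> float:
    labels = np.asarray(labels)
    preds = (np.asarray(scores) >= threshold).astype(int)
    return float((preds == labels).mean())


def top_n_hit_rate(
    labels: np.ndarray,
    scores: np.ndarray,
    n: int = 100,
    ids: Sequence[str] | None = None,
) -> tuple[float, int, int]:
    """Percentage of true actives among the n highest-scored items.

    Ties in score break by id (ascending) for reproducibility; when the set
    is smaller than n the rate is computed over the whole set with a
    warning. Returns (hit rate percent, TP, FP).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if labels.size == 0:
        raise ValueError("empty input")
    if ids is None:
        ids = [str(i) for i in range(labels.size)]
    if labels.size < n:
        warnings.warn(
            f"top-{n} requested on {labels.size} items; using all of them"
        )
    order = sorted(range(labels.size), key=lambda i: (-scores[i], ids[i]))
    top = order[: min(n, labels.size)]
    tp = int(labels[top].sum())
    fp = len(top) - tp
    return 100.0 * tp / (tp + fp), tp, fp


def performance_gap(result: EvalResult) -> tuple[float, float]:
    """(gap_auc, gap_acc) with the ID − OOD sign convention: positive means
    degradation out of distribution."""
    return result.gap_auc, result.gap_acc


# ---------------------------------------------------------------------------
# harness


def train_and_evaluate(
    model: ModelAdapter,
    split: DatasetSplit,
    records: Sequence[MoleculeRecord],
    featurizer=None,
    top_n: int = 100,
) -> EvalResult:
    """Fit on the training set and score the ID and OOD test sets.

    One model is fitted once; the same fit produces both ID and OOD
    metrics, so any gap reflects the data shift alone. ``featurizer`` maps a
    record list to a feature matrix (default: ECFP4, 2048 bits). Metric
    failures on a subset (e.g. a single-class OOD test set) surface as NaN
    for that metric; the remaining metrics are still computed.
    """
    if featurizer is None:
        featurizer = lambda recs: ecfp_matrix(recs, radius=2, n_bits=2048)
    by_id = {r.id: r for r in records}

    def subset(id_set):
        recs = [by_id[i] for i in sorted(id_set)]
        return recs, featurizer(recs), np.array([r.label for r in recs])

    train_recs, X_train, y_train = subset(split.train)
    _, X_id, y_id = subset(split.id_test)
    ood_recs, X_ood, y_ood = subset(split.ood_test)
    model.fit(X_train, y_train)
    s_id = model.predict_scores(X_id)
    s_ood = model.predict_scores(X_ood)

    def safe_auc(y, s):
        try:
            return roc_auc(y, s)
        except ValueError:
            return float("nan")

    hit_rate, tp, fp = top_n_hit_rate(
        y_ood, s_ood, n=top_n, ids=[r.id for r in ood_recs]
    )
    return EvalResult(
        model_name=getattr(model, "name", type(model).__name__),
        roc_auc_id=safe_auc(y_id, s_id),
        roc_auc_ood=safe_auc(y_ood, s_ood),
        accuracy_id=accuracy(y_id, s_id),
        accuracy_ood=accuracy(y_ood, s_ood),
        hit_rate_ood=hit_rate,
        top_n_tp=tp,
        top_n_fp=fp,
        provenance=dict(split.provenance),
    )
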