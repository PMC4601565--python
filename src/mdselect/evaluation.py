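"""Problem-transformation benchmark harness.

A multidimensional problem is decomposed into ``m`` independent
single-target classification problems, one per class variable; any
single-target trainer satisfying :data:`TrainerContract` can be plugged
in.  :func:`compare_selection` evaluates each trainer under two
conditions — all features (``before_selection``) and the selected subset
(``after_selection``) — with the subset recomputed from training folds
only, so no test information leaks into the selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .core import SelectionResult, select
from .datasets import MDDataset
from .errors import ConfigurationError, ValidationError
from .metrics import MetricSet, compute_metrics

__all__ = [
    "TrainerContract",
    "Predictor",
    "EvaluationProtocol",
    "BenchmarkReport",
    "TRAINER_REGISTRY",
    "make_trainer",
    "fit_multidimensional",
    "compare_selection",
]

#: A predictor maps a feature matrix to one predicted class column.
Predictor = Callable[[np.ndarray], np.ndarray]

#: A trainer maps (feature matrix, integer class column, seed) to a predictor.
TrainerContract = Callable[[np.ndarray, np.ndarray, int], Predictor]


class MultiPredictor:
    """m per-class-variable predictors applied column-wise."""

    def __init__(self, predictors: list[Predictor]):
        self.predictors = predictors

    def predict(self, features: np.ndarray) -> np.ndarray:
        columns = [p(features) for p in self.predictors]
        return np.column_stack(columns)


def fit_multidimensional(
    data: MDDataset, trainer: TrainerContract, seed: int = 0
) -> MultiPredictor:
    """Train one single-target predictor per class variable.

    Class values are integer-encoded by domain position; predictions are
    emitted in the same encoding.
    """
    encoded = data.encoded_targets()
    predictors = []
    for i in range(data.m):
        try:
            predictors.append(trainer(data.features, encoded[:, i], seed))
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise ValidationError(
                f"trainer failed on class variable {data.class_names[i]!r}: {exc}"
            ) from exc
    return MultiPredictor(predictors)


# ---------------------------------------------------------------------------
# Trainer registry


def _majority_trainer(x: np.ndarray, y: np.ndarray, seed: int) -> Predictor:
    values, counts = np.unique(y, return_counts=True)
    label = values[np.argmax(counts)]
    return lambda features: np.full(features.shape[0], label, dtype=int)


def _nearest_centroid_trainer(x: np.ndarray, y: np.ndarray, seed: int) -> Predictor:
    labels = np.unique(y)
    centroids = np.stack([x[y == lab].mean(axis=0) for lab in labels])

    def predict(features: np.ndarray) -> np.ndarray:
        d = ((features[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        return labels[np.argmin(d, axis=1)]

    return predict


def _sklearn_trainer(factory: Callable[[int], object]) -> TrainerContract:
    def trainer(x: np.ndarray, y: np.ndarray, seed: int) -> Predictor:
        model = factory(seed)
        model.fit(x, y)
        return lambda features: np.asarray(model.predict(features))

    return trainer


def _decision_tree(seed: int):
    from sklearn.tree import DecisionTreeClassifier

    return DecisionTreeClassifier(random_state=seed)


def _naive_bayes(seed: int):
    from sklearn.naive_bayes import GaussianNB

    return GaussianNB()


def _linear_svm(seed: int):
    from sklearn.svm import LinearSVC

    return LinearSVC(random_state=seed, dual="auto")


def _knn(seed: int):
    from sklearn.neighbors import KNeighborsClassifier

    return KNeighborsClassifier(n_neighbors=3)


def _logistic(seed: int):
    from sklearn.linear_model import LogisticRegression

    return LogisticRegression(random_state=seed, max_iter=1000)


TRAINER_REGISTRY: dict[str, TrainerContract] = {
    "majority": _majority_trainer,
    "nearest_centroid": _nearest_centroid_trainer,
    "decision_tree": _sklearn_trainer(_decision_tree),
    "naive_bayes": _sklearn_trainer(_naive_bayes),
    "linear_svm": _sklearn_trainer(_linear_svm),
    "knn": _sklearn_trainer(_knn),
    "logistic": _sklearn_trainer(_logistic),
}


def make_trainer(name: str) -> TrainerContract:
    try:
        return TRAINER_REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown trainer {name!r}; known: {sorted(TRAINER_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# Benchmark protocol


@dataclass(frozen=True)
class EvaluationProtocol:
    """k-fold cross-validation (default) or a single holdout split."""

    n_folds: int = 10
    holdout_fraction: float | None = None  # if set, a single split instead
    seed: int = 0

    def __post_init__(self) -> None:
        if self.holdout_fraction is not None:
            if not 0 < self.holdout_fraction < 1:
                raise ConfigurationError("holdout_fraction must be in (0, 1)")
        elif self.n_folds < 2:
            raise ConfigurationError("need at least 2 folds")


@dataclass
class BenchmarkReport:
    """Metrics per (classifier, condition) plus run provenance."""

    results: dict[tuple[str, str], MetricSet]
    selections: list[SelectionResult]
    protocol: EvaluationProtocol
    subset_size: int
    conditions: tuple[str, str] = ("before_selection", "after_selection")
    feature_names: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = []
        for (classifier, condition), ms in self.results.items():
            rows.append(
                {"classifier": classifier, "condition": condition, **ms.as_dict()}
            )
        return pd.DataFrame(rows)


def _splits(n: int, protocol: EvaluationProtocol):
    rng = np.random.default_rng(protocol.seed)
    order = rng.permutation(n)
    if protocol.holdout_fraction is not None:
        n_test = max(1, int(round(protocol.holdout_fraction * n)))
        yield order[n_test:], order[:n_test]
        return
    folds = np.array_split(order, protocol.n_folds)
    for k, test in enumerate(folds):
        train = np.concatenate([f for j, f in enumerate(folds) if j != k])
        yield train, test


def compare_selection(
    data: MDDataset,
    trainers: Mapping[str, TrainerContract],
    protocol: EvaluationProtocol | None = None,
    s: int | None = None,
    absolute: bool = False,
) -> BenchmarkReport:
    """Evaluate every trainer with all features and with the selected subset.

    Selection is recomputed on each training split and the same subset is
    shared by every trainer and class variable within the split; metrics
    are pooled over held-out predictions.
    """
    if protocol is None:
        protocol = EvaluationProtocol()
    if not trainers:
        raise ConfigurationError("no trainers given")
    encoded = data.encoded_targets()
    true_pool: list[np.ndarray] = []
    pred_pool: dict[tuple[str, str], list[np.ndarray]] = {}
    selections: list[SelectionResult] = []
    s_used: int | None = None

    for train_idx, test_idx in _splits(data.n, protocol):
        if train_idx.size < 2:
            raise ConfigurationError("protocol leaves fewer than 2 training instances")
        train_data = _take(data, train_idx)
        selection = select(train_data, s=s, absolute=absolute)
        selections.append(selection)
        s_used = selection.s
        sel = selection.selected
        true_pool.append(encoded[test_idx])
        for name, trainer in trainers.items():
            full_model = fit_multidimensional(train_data, trainer, protocol.seed)
            sub_model = fit_multidimensional(
                train_data.subset_features(sel), trainer, protocol.seed
            )
            pred_pool.setdefault((name, "before_selection"), []).append(
                full_model.predict(data.features[test_idx])
            )
            pred_pool.setdefault((name, "after_selection"), []).append(
                sub_model.predict(data.features[test_idx][:, sel])
            )

    true = np.vstack(true_pool)
    results = {
        key: compute_metrics(true, np.vstack(preds))
        for key, preds in pred_pool.items()
    }
    return BenchmarkReport(
        results=results,
        selections=selections,
        protocol=protocol,
        subset_size=int(s_used or 0),
        feature_names=list(data.feature_names),
    )


def _take(data: MDDataset, idx: np.ndarray) -> MDDataset:
    return MDDataset(
        features=data.features[idx],
        targets=data.targets[idx],
        feature_names=list(data.feature_names),
        class_names=list(data.class_names),
        class_domains=[list(d) for d in data.class_domains],
        feature_domains=list(data.feature_domains),
    )
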