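"""Raw and single-scale (LLT) baseline representations, plus a built-in
nearest-neighbor classifier so end-to-end evaluation needs no external
learner.

LLT — the earlier single-scale law-based transformation — is by
definition the multiscale pipeline restricted to a one-element schedule,
and is implemented as exactly that, so the two paths are byte-identical
on a single triplet.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np

from .datasets import TimeSeriesDataset
from .errors import ConfigurationError, DatasetError
from .laws import LTSplitConfig
from .schedule import Schedule, ScheduleTriplet
from .transform import ALTModel, FeatureTable, PoolingSpec

__all__ = ["ClassifierInterface", "KNNClassifier", "llt_fit", "llt_transform",
           "raw_features", "knn_fit_predict", "evaluate_accuracy"]


@runtime_checkable
class ClassifierInterface(Protocol):
    """Minimal classifier contract: fit features, predict labels."""

    name: str

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierInterface": ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...


class KNNClassifier:
    """k-nearest neighbors with fully deterministic tie-breaking.

    Euclidean distance, majority vote. Distance ties are broken by the
    lowest training index (stable sort); vote ties by the smallest
    class label.
    """

    def __init__(self, k: int = 1):
        if k < 1:
            raise ConfigurationError(f"k must be >= 1, got {k}")
        self.k = k
        self.name = f"knn{k}"
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, X, y) -> "KNNClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.intp)
        if X.ndim != 2 or X.shape[0] == 0:
            raise DatasetError("training features must be a non-empty 2-D array")
        if y.shape != (X.shape[0],):
            raise DatasetError("labels must align with feature rows")
        if self.k > X.shape[0]:
            raise ConfigurationError(
                f"k={self.k} exceeds training size {X.shape[0]}")
        self._X, self._y = X, y
        return self

    def predict(self, X) -> np.ndarray:
        if self._X is None:
            raise ConfigurationError("predict called before fit")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        d2 = ((X[:, None, :] - self._X[None, :, :]) ** 2).sum(axis=2)
        # stable argsort: equal distances resolve to the lowest index
        nn = np.argsort(d2, axis=1, kind="stable")[:, : self.k]
        votes = self._y[nn]
        out = np.empty(X.shape[0], dtype=np.intp)
        for i in range(X.shape[0]):
            counts = np.bincount(votes[i])
            out[i] = int(np.argmax(counts))  # first max = smallest label
        return out


def knn_fit_predict(train_X, train_y, test_X, k: int = 1) -> np.ndarray:
    """One-shot convenience wrapper around :class:`KNNClassifier`."""
    return KNNClassifier(k=k).fit(train_X, train_y).predict(test_X)


def llt_fit(ds: TimeSeriesDataset, triplet: ScheduleTriplet,
            specs: list[PoolingSpec],
            lt_config: LTSplitConfig = LTSplitConfig()) -> ALTModel:
    """Train the single-scale baseline: the pipeline on a one-triplet
    schedule. A multi-triplet input is an error by definition."""
    if isinstance(triplet, (Schedule, list, tuple)) and not (
            isinstance(triplet, tuple) and len(triplet) == 3
            and all(isinstance(v, (int, np.integer)) for v in triplet)):
        raise ConfigurationError(
            "the single-scale baseline takes exactly one triplet; "
            "use ALTModel.fit with a Schedule for multiscale")
    if not isinstance(triplet, ScheduleTriplet):
        triplet = ScheduleTriplet(*triplet)
    return ALTModel.fit(ds, Schedule([triplet]), specs, lt_config)


def llt_transform(ds: TimeSeriesDataset, triplet: ScheduleTriplet,
                  specs: list[PoolingSpec],
                  lt_config: LTSplitConfig = LTSplitConfig()) -> FeatureTable:
    """Fit the single-scale baseline on ``ds`` and transform ``ds``."""
    return llt_fit(ds, triplet, specs, lt_config).transform(ds)


def raw_features(ds: TimeSeriesDataset) -> FeatureTable:
    """Concatenated per-channel samples as the feature vector (m * H).

    Requires equal-length instances; variable lengths need the law-based
    transformation, which produces fixed-length features regardless of H.
    """
    if not ds.equal_length:
        raise DatasetError(
            "raw features require equal-length instances; use the "
            "law-based transformation for variable-length series")
    H = int(ds.lengths[0])
    values = np.vstack([x.reshape(-1) for x in ds.instances])
    names = [f"raw|ch{j}|x{t}" for j in range(ds.n_channels) for t in range(H)]
    return FeatureTable(values=values, names=names, labels=ds.labels.copy(),
                        instance_ids=np.arange(ds.n_instances))


def evaluate_accuracy(pred, true) -> float:
    """Exact-match fraction in [0, 1]."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape or pred.size == 0:
        raise DatasetError("prediction and truth must be equal-length, non-empty")
    return float(np.mean(pred == true))
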