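"""Shapelet-law extraction and class-labeled dictionaries.

A *shapelet law* is the unit eigenvector of a window's symmetric delay
embedding ``S`` associated with the eigenvalue of minimal magnitude —
the direction ``v`` minimizing ``||S v||`` over unit vectors. For each
channel and schedule triplet, the laws of all law-training (LT) windows
are collected column-wise into a dictionary ``P`` (l x N); each column
carries the class label of its source instance.

Tie-breaking (the argmin over ``|lambda|`` is ill-posed for, e.g.,
constant windows): among eigenvalues whose magnitude is within
``1e-12 * max(1, ||S||)`` of the minimum, take the smallest signed
eigenvalue; residual degeneracy falls back to the first such position in
ascending eigenvalue order. The sign of ``v`` is normalized so its
largest-magnitude entry (lowest index on ties) is positive. Downstream
responses are squared, so the sign only matters for reproducibility of
stored dictionaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .datasets import TimeSeriesDataset
from .errors import ConfigurationError, DatasetError, NumericError
from .schedule import (Schedule, ScheduleTriplet, SymmetricEmbedding,
                       build_embedding_matrix, enumerate_window_starts)

__all__ = ["LawVector", "LawDictionary", "LTSplitConfig", "extract_law",
           "split_law_training", "build_dictionaries"]

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class LawVector:
    """Unit-norm law with its eigenvalue and provenance."""

    v: np.ndarray
    lambda_min: float
    class_label: int | None = None
    source: tuple = ()


@dataclass(frozen=True)
class LawDictionary:
    """Class-labeled law dictionary for one (channel, triplet).

    ``P`` is l x N with unit-norm columns in deterministic order
    (LT-instance order, then window-start order); ``pi`` holds the N
    class labels in 1..c.
    """

    P: np.ndarray
    pi: np.ndarray
    channel: int
    triplet: ScheduleTriplet

    @property
    def N(self) -> int:
        return self.P.shape[1]

    @property
    def l(self) -> int:
        return self.P.shape[0]


def extract_law(S, class_label: int | None = None, source: tuple = ()) -> LawVector:
    """Eigenvector of minimal-|eigenvalue| of a symmetric matrix.

    Accepts a :class:`SymmetricEmbedding` or a raw l x l array. The
    input must be finite and symmetric to ``1e-10`` relative tolerance.
    """
    if isinstance(S, SymmetricEmbedding):
        if not source:
            source = S.source
        S = S.values
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise NumericError(f"expected a square matrix, got shape {S.shape}")
    if not np.all(np.isfinite(S)):
        raise NumericError("matrix contains non-finite entries")
    scale = np.linalg.norm(S)
    if np.linalg.norm(S - S.T) > 1e-10 * max(1.0, scale):
        raise NumericError("matrix is not symmetric")

    lam, V = eigh(S)  # ascending eigenvalues, orthonormal columns
    absmin = np.abs(lam).min()
    tol = _TIE_RTOL * max(1.0, scale)
    candidates = np.flatnonzero(np.abs(lam) <= absmin + tol)
    # smallest signed eigenvalue among magnitude-ties; eigh's ascending
    # order makes that the first candidate
    idx = int(candidates[0])
    v = V[:, idx].copy()
    # sign convention: largest-|entry| positive, lowest index on ties
    pivot = int(np.argmax(np.abs(v)))
    if v[pivot] < 0:
        v = -v
    v /= np.linalg.norm(v)
    return LawVector(v=v, lambda_min=float(lam[idx]),
                     class_label=class_label, source=source)


@dataclass(frozen=True)
class LTSplitConfig:
    """Law-training split: fraction ``rho`` of training instances build
    the dictionaries; the rest train the downstream classifier."""

    rho: float = 0.25
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.rho <= 1.0:
            raise ConfigurationError(f"rho must be in (0, 1], got {self.rho}")


def split_law_training(
    ds: TimeSeriesDataset, cfg: LTSplitConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Partition training-instance ids into (LT ids, classifier ids).

    Stratified (default): per class the LT count is
    ``max(1, floor(rho * n_class))``, so every class contributes at
    least one law source. ``rho = 1`` returns all ids in both roles (the
    only non-degenerate reading; a warning is emitted).
    """
    rng = np.random.default_rng(cfg.seed)
    all_ids = np.arange(ds.n_instances)
    if cfg.rho == 1.0:
        import warnings

        warnings.warn(
            "rho=1: law-training instances are re-used for classifier training",
            stacklevel=2)
        return all_ids.copy(), all_ids.copy()
    lt_ids: list[int] = []
    if cfg.stratified:
        for cls in range(1, ds.n_classes + 1):
            ids = np.flatnonzero(ds.labels == cls)
            if ids.size == 0:
                raise DatasetError(f"class {cls} has no instances")
            n_lt = max(1, int(np.floor(cfg.rho * ids.size)))
            perm = rng.permutation(ids)
            lt_ids.extend(perm[:n_lt].tolist())
    else:
        n_lt = max(1, int(np.floor(cfg.rho * ds.n_instances)))
        perm = rng.permutation(all_ids)
        lt_ids = perm[:n_lt].tolist()
    lt = np.array(sorted(lt_ids), dtype=np.intp)
    clf = np.setdiff1d(all_ids, lt)
    return lt, clf


def expected_dictionary_size(
    lengths, trip: ScheduleTriplet
) -> int:
    """Closed-form N = sum_i (floor((h_i - r)/k) + 1) over LT instances."""
    lengths = np.asarray(lengths, dtype=np.intp)
    return int(np.sum((lengths - trip.r) // trip.k + 1))


def build_dictionaries(
    ds: TimeSeriesDataset,
    lt_ids,
    schedule: Schedule,
) -> dict[tuple[int, ScheduleTriplet], LawDictionary]:
    """Extract laws from every LT window and assemble dictionaries.

    Returns one :class:`LawDictionary` per (channel, triplet), keyed by
    ``(channel, triplet)``. Any class ending up with zero laws for some
    dictionary is a configuration error: class-wise pooling is undefined
    over zero columns.
    """
    lt_ids = np.asarray(lt_ids, dtype=np.intp)
    if lt_ids.size == 0:
        raise ConfigurationError("law-training id set is empty")
    min_h = min(ds.instances[i].shape[1] for i in lt_ids)
    if schedule.max_r > min_h:
        raise DatasetError(
            f"max window length r={schedule.max_r} exceeds the shortest "
            f"law-training instance (h={min_h})")
    dicts: dict[tuple[int, ScheduleTriplet], LawDictionary] = {}
    for trip in schedule:
        for j in range(ds.n_channels):
            cols: list[np.ndarray] = []
            labels: list[int] = []
            for i in lt_ids:
                x = ds.instances[i][j]
                y = int(ds.labels[i])
                for t in enumerate_window_starts(x.size, trip):
                    emb = build_embedding_matrix(x, int(t), trip,
                                                 source=(int(i), j, int(t), trip))
                    law = extract_law(emb, class_label=y)
                    cols.append(law.v)
                    labels.append(y)
            P = np.column_stack(cols)
            pi = np.asarray(labels, dtype=np.intp)
            present = set(pi.tolist())
            missing = sorted(set(range(1, ds.n_classes + 1)) - present)
            if missing:
                raise ConfigurationError(
                    f"classes {missing} contributed no laws for channel {j}, "
                    f"triplet {trip}; increase rho or adjust the schedule")
            dicts[(j, trip)] = LawDictionary(P=P, pi=pi, channel=j, triplet=trip)
    return dicts
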