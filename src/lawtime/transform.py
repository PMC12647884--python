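"""Projection onto law dictionaries and two-stage pooling into features.

An instance's channel is unrolled into strided row embeddings ``A``
(o x l) and projected onto the matching dictionary, ``M = A @ P``
(o x N). Responses are squared (energy) and pooled in two stages:

1. *across laws*: within each window row, a mean or q-quantile over the
   squared responses of the columns belonging to one class;
2. *across windows*: a population moment (mean, variance, third/fourth
   central moment, or excess kurtosis) over the resulting o-sequence.

One scalar per (triplet, channel, class, pooling pair) gives a feature
vector of length ``|R| * m * c * n``. Column order is deterministic:
schedule order, then channel, then class, then pooling pair, with names
``t{idx}_r{r}_l{l}_k{k}|ch{j}|class{c}|{pair}``.

Quantiles use linear interpolation between order statistics (the common
"type 7" convention). Moments are population moments (divide by o, no
bias correction). Excess kurtosis of a near-constant sequence
(``m2 <= 1e-24 * scale``) is defined as 0 to avoid NaN features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import TimeSeriesDataset
from .errors import PoolingError, TransformError
from .laws import (LawDictionary, LTSplitConfig, build_dictionaries,
                   split_law_training)
from .schedule import (Schedule, ScheduleTriplet, build_row_embeddings,
                       validate_triplet)

__all__ = ["PoolingSpec", "ResponseMatrix", "FeatureTable", "ALTModel",
           "law_responses", "pool_across_laws", "pool_across_windows",
           "transform_instance"]

_ACROSS_LAWS = ("mean", "quantile")
_ACROSS_WINDOWS = ("mean", "variance", "m3", "m4", "excess_kurtosis")
_KURT_TOL = 1e-24


@dataclass(frozen=True)
class PoolingSpec:
    """One pooling pair: across-laws statistic then across-windows moment.

    ``across_laws`` is ``"mean"`` or ``"quantile"`` (with ``q`` in
    [0, 1]); ``across_windows`` is one of mean, variance, m3, m4,
    excess_kurtosis. Both stages act on squared responses.
    """

    across_laws: str = "mean"
    q: float | None = None
    across_windows: str = "mean"

    def __post_init__(self) -> None:
        if self.across_laws not in _ACROSS_LAWS:
            raise PoolingError(f"unknown across-laws statistic {self.across_laws!r}")
        if self.across_laws == "quantile":
            if self.q is None or not 0.0 <= self.q <= 1.0:
                raise PoolingError(f"quantile level must be in [0, 1], got {self.q}")
        elif self.q is not None:
            raise PoolingError("q is only meaningful with across_laws='quantile'")
        if self.across_windows not in _ACROSS_WINDOWS:
            raise PoolingError(
                f"unknown across-windows statistic {self.across_windows!r}")

    @property
    def name(self) -> str:
        if self.across_laws == "quantile":
            pct = self.q * 100
            first = f"p{pct:05.2f}".rstrip("0").rstrip(".") if pct % 1 else f"p{int(pct):02d}"
        else:
            first = "mean"
        return f"{first}-{self.across_windows}"

    @classmethod
    def from_string(cls, text: str) -> "PoolingSpec":
        """Parse names like ``"mean-mean"``, ``"p05-variance"``,
        ``"p05-m4"``."""
        try:
            first, second = text.strip().split("-", 1)
        except ValueError:
            raise PoolingError(f"cannot parse pooling pair {text!r}")
        if first == "mean":
            return cls("mean", None, second)
        if first.startswith("p"):
            return cls("quantile", float(first[1:]) / 100.0, second)
        raise PoolingError(f"cannot parse across-laws statistic {first!r}")


@dataclass(frozen=True)
class ResponseMatrix:
    """o x N law responses of one channel/triplet of one instance."""

    M: np.ndarray
    channel: int
    triplet: ScheduleTriplet
    pi: np.ndarray  # dictionary class labels, length N


def law_responses(A, D: LawDictionary) -> ResponseMatrix:
    """``M = A @ P``: inner products of rows with dictionary laws."""
    from .schedule import RowEmbeddingMatrix

    if isinstance(A, RowEmbeddingMatrix):
        if A.triplet != D.triplet:
            raise TransformError(
                f"row embeddings {A.triplet} do not match dictionary {D.triplet}")
        if A.channel != D.channel:
            raise TransformError(
                f"channel mismatch: rows ch{A.channel} vs dictionary ch{D.channel}")
        A = A.values
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[1] != D.l:
        raise TransformError(
            f"row embeddings have width {A.shape[-1]}, dictionary expects {D.l}")
    return ResponseMatrix(M=A @ D.P, channel=D.channel, triplet=D.triplet,
                          pi=D.pi)


def pool_across_laws(M: ResponseMatrix, target_class: int,
                     spec: PoolingSpec) -> np.ndarray:
    """Per-window statistic of squared responses of one class's laws."""
    mask = M.pi == target_class
    if not mask.any():
        raise PoolingError(f"no dictionary columns labeled class {target_class}")
    E = M.M[:, mask] ** 2
    if spec.across_laws == "mean":
        return E.mean(axis=1)
    return np.quantile(E, spec.q, axis=1, method="linear")


def _central_moments(seq: np.ndarray) -> tuple[float, float, float, float]:
    mu = float(seq.mean())
    d = seq - mu
    return mu, float(np.mean(d**2)), float(np.mean(d**3)), float(np.mean(d**4))


def pool_across_windows(seq, spec: PoolingSpec) -> float:
    """Population moment of the per-window sequence."""
    seq = np.asarray(seq, dtype=np.float64)
    if seq.size == 0:
        raise PoolingError("cannot pool an empty window sequence")
    mu, m2, m3, m4 = _central_moments(seq)
    if spec.across_windows == "mean":
        return mu
    if spec.across_windows == "variance":
        return m2
    if spec.across_windows == "m3":
        return m3
    if spec.across_windows == "m4":
        return m4
    # excess kurtosis, with the degenerate near-constant rule
    scale = max(1.0, mu * mu)
    if m2 <= _KURT_TOL * scale:
        return 0.0
    return m4 / (m2 * m2) - 3.0


@dataclass
class FeatureTable:
    """Fixed-length feature vectors with deterministic column names."""

    values: np.ndarray  # (instances, D)
    names: list[str]
    labels: np.ndarray | None = None
    instance_ids: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        if self.instance_ids is not None:
            df.insert(0, "instance", self.instance_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def feature_names(schedule: Schedule, n_channels: int, n_classes: int,
                  specs: list[PoolingSpec]) -> list[str]:
    names = []
    for idx, trip in enumerate(schedule):
        for j in range(n_channels):
            for cls in range(1, n_classes + 1):
                for spec in specs:
                    names.append(
                        f"t{idx}_r{trip.r}_l{trip.l}_k{trip.k}"
                        f"|ch{j}|class{cls}|{spec.name}")
    return names


def transform_instance(instance: np.ndarray, dictionaries, schedule: Schedule,
                       specs: list[PoolingSpec], n_classes: int) -> np.ndarray:
    """Feature vector of one (m, H) instance; deterministic order."""
    x = np.atleast_2d(np.asarray(instance, dtype=np.float64))
    H = x.shape[1]
    for trip in schedule:
        if H < trip.r:
            raise TransformError(
                f"instance of length {H} is shorter than window length "
                f"r={trip.r} of triplet {trip}")
    out: list[float] = []
    for trip in schedule:
        for j in range(x.shape[0]):
            A = build_row_embeddings(x[j], trip, channel=j)
            M = law_responses(A, dictionaries[(j, trip)])
            for cls in range(1, n_classes + 1):
                for spec in specs:
                    seq = pool_across_laws(M, cls, spec)
                    out.append(pool_across_windows(seq, spec))
    return np.asarray(out, dtype=np.float64)


class ALTModel:
    """A trained adaptive law-based transformation.

    Holds the class-labeled law dictionaries for every (channel,
    triplet), the schedule, the pooling specs and the LT split used in
    training. ``transform`` maps any dataset (or single instance) to
    the fixed-length feature representation.
    """

    def __init__(self, schedule: Schedule, specs: list[PoolingSpec],
                 dictionaries: dict, n_channels: int, n_classes: int,
                 class_names: list[str], lt_ids=None, clf_ids=None,
                 lt_config: LTSplitConfig | None = None):
        self.schedule = schedule
        self.specs = list(specs)
        self.dictionaries = dictionaries
        self.n_channels = n_channels
        self.n_classes = n_classes
        self.class_names = list(class_names)
        self.lt_ids = None if lt_ids is None else np.asarray(lt_ids, dtype=np.intp)
        self.clf_ids = None if clf_ids is None else np.asarray(clf_ids, dtype=np.intp)
        self.lt_config = lt_config

    # -- training ------------------------------------------------------
    @classmethod
    def fit(cls, ds: TimeSeriesDataset, schedule: Schedule,
            specs: list[PoolingSpec],
            lt_config: LTSplitConfig = LTSplitConfig()) -> "ALTModel":
        """Split LT/classifier instances, extract laws, build dictionaries."""
        if ds.min_length < schedule.max_r:
            raise TransformError(
                f"shortest training instance (h={ds.min_length}) is shorter "
                f"than the largest window length r={schedule.max_r}")
        lt_ids, clf_ids = split_law_training(ds, lt_config)
        dicts = build_dictionaries(ds, lt_ids, schedule)
        return cls(schedule=schedule, specs=specs, dictionaries=dicts,
                   n_channels=ds.n_channels, n_classes=ds.n_classes,
                   class_names=ds.class_names, lt_ids=lt_ids, clf_ids=clf_ids,
                   lt_config=lt_config)

    # -- application ---------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return feature_names(self.schedule, self.n_channels, self.n_classes,
                             self.specs)

    @property
    def n_features(self) -> int:
        return len(self.schedule) * self.n_channels * self.n_classes * len(self.specs)

    def transform(self, ds: TimeSeriesDataset) -> FeatureTable:
        if ds.n_channels != self.n_channels:
            raise TransformError(
                f"dataset has {ds.n_channels} channels, model expects "
                f"{self.n_channels}")
        rows = [transform_instance(x, self.dictionaries, self.schedule,
                                   self.specs, self.n_classes)
                for x in ds.instances]
        return FeatureTable(values=np.vstack(rows), names=self.feature_names,
                            labels=ds.labels.copy(),
                            instance_ids=np.arange(ds.n_instances))

    def transform_instance(self, instance) -> np.ndarray:
        return transform_instance(instance, self.dictionaries, self.schedule,
                                  self.specs, self.n_classes)

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        """Serialize to a single ``.npz`` archive (arrays + JSON manifest);
        round-trips bit-exactly."""
        arrays: dict[str, np.ndarray] = {}
        entries = []
        for idx, ((j, trip), D) in enumerate(sorted(
                self.dictionaries.items(),
                key=lambda kv: (kv[0][0], kv[0][1].r, kv[0][1].l, kv[0][1].k))):
            arrays[f"P_{idx}"] = D.P
            arrays[f"pi_{idx}"] = D.pi
            entries.append({"index": idx, "channel": j,
                            "triplet": [trip.r, trip.l, trip.k], "N": D.N})
        manifest = {
            "format": "lawtime-alt-model",
            "version": 1,
            "schedule": [[t.r, t.l, t.k] for t in self.schedule],
            "specs": [{"across_laws": s.across_laws, "q": s.q,
                       "across_windows": s.across_windows} for s in self.specs],
            "n_channels": self.n_channels,
            "n_classes": self.n_classes,
            "class_names": self.class_names,
            "lt_ids": None if self.lt_ids is None else self.lt_ids.tolist(),
            "clf_ids": None if self.clf_ids is None else self.clf_ids.tolist(),
            "lt_config": None if self.lt_config is None else {
                "rho": self.lt_config.rho, "seed": self.lt_config.seed,
                "stratified": self.lt_config.stratified},
            "dictionaries": entries,
        }
        arrays["manifest"] = np.frombuffer(
            json.dumps(manifest).encode("utf-8"), dtype=np.uint8)
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path) -> "ALTModel":
        with np.load(Path(path)) as npz:
            manifest = json.loads(bytes(npz["manifest"].tobytes()).decode("utf-8"))
            if manifest.get("format") != "lawtime-alt-model":
                raise TransformError(f"{path} is not a lawtime model archive")
            schedule = Schedule([validate_triplet(*t) for t in manifest["schedule"]])
            specs = [PoolingSpec(s["across_laws"], s["q"], s["across_windows"])
                     for s in manifest["specs"]]
            dicts = {}
            for e in manifest["dictionaries"]:
                trip = validate_triplet(*e["triplet"])
                dicts[(e["channel"], trip)] = LawDictionary(
                    P=npz[f"P_{e['index']}"].copy(),
                    pi=npz[f"pi_{e['index']}"].copy(),
                    channel=e["channel"], triplet=trip)
            lt_cfg = manifest["lt_config"]
            return cls(
                schedule=schedule, specs=specs, dictionaries=dicts,
                n_channels=manifest["n_channels"],
                n_classes=manifest["n_classes"],
                class_names=manifest["class_names"],
                lt_ids=manifest["lt_ids"], clf_ids=manifest["clf_ids"],
                lt_config=None if lt_cfg is None else LTSplitConfig(**lt_cfg))
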