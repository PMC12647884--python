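"""Labeled time-series datasets: container, UCR ``.ts`` and long-CSV I/O,
and seeded stratified resampling.

A dataset holds ``tau`` instances; instance ``i`` is an ``(m, h_i)``
array (``m`` channels, per-instance length ``h_i`` that may vary across
instances but is shared by the channels of one instance). Labels are
encoded 1..c in first-appearance order of the file's class tokens; the
original tokens are kept in ``class_names``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DatasetError, ParseError

__all__ = ["TimeSeriesDataset", "read_ts", "write_ts", "read_csv_long",
           "write_csv_long", "resample_split"]


@dataclass
class TimeSeriesDataset:
    """Labeled collection of multichannel series.

    Parameters
    ----------
    instances : list of (m, h_i) float arrays
    labels : int array in 1..c, one per instance
    class_names : original class tokens, index ``label - 1``
    name : dataset name (metadata only)
    """

    instances: list[np.ndarray]
    labels: np.ndarray
    class_names: list[str] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.instances = [np.atleast_2d(np.asarray(x, dtype=np.float64))
                          for x in self.instances]
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if len(self.instances) == 0:
            raise DatasetError("dataset has no instances")
        if self.labels.shape != (len(self.instances),):
            raise DatasetError("labels must align with instances")
        m = self.instances[0].shape[0]
        for i, x in enumerate(self.instances):
            if x.ndim != 2 or x.shape[0] != m:
                raise DatasetError(
                    f"instance {i} has {x.shape[0]} channels, expected {m}")
            if x.shape[1] < 1:
                raise DatasetError(f"instance {i} has zero length")
            if not np.all(np.isfinite(x)):
                raise DatasetError(f"instance {i} contains non-finite values")
        c = int(self.labels.max(initial=0))
        if self.labels.min(initial=1) < 1:
            raise DatasetError("labels must be >= 1")
        present = set(self.labels.tolist())
        missing = sorted(set(range(1, c + 1)) - present)
        if missing:
            raise DatasetError(f"empty classes: {missing}")
        if not self.class_names:
            self.class_names = [str(i) for i in range(1, c + 1)]
        if len(self.class_names) != c:
            raise DatasetError("class_names must have one entry per class")

    # -- basic queries -------------------------------------------------
    @property
    def n_instances(self) -> int:
        return len(self.instances)

    @property
    def n_channels(self) -> int:
        return self.instances[0].shape[0]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    @property
    def lengths(self) -> np.ndarray:
        return np.array([x.shape[1] for x in self.instances], dtype=np.intp)

    @property
    def min_length(self) -> int:
        return int(self.lengths.min())

    @property
    def equal_length(self) -> bool:
        return bool(np.all(self.lengths == self.lengths[0]))

    def subset(self, ids: Sequence[int], name: str | None = None) -> "TimeSeriesDataset":
        ids = list(ids)
        return TimeSeriesDataset(
            instances=[self.instances[i].copy() for i in ids],
            labels=self.labels[ids].copy(),
            class_names=list(self.class_names),
            name=name or self.name,
        )

    def copy(self) -> "TimeSeriesDataset":
        return self.subset(range(self.n_instances))


# ---------------------------------------------------------------------
# UCR .ts dialect
# ---------------------------------------------------------------------

def read_ts(path) -> TimeSeriesDataset:
    """Read a dataset in the UCR ``.ts`` text dialect.

    Recognized header tags: ``@problemName``, ``@univariate``,
    ``@dimensions``, ``@classLabel``, plus the tolerated
    ``@equalLength``, ``@seriesLength``, ``@timeStamps``, ``@missing``.
    Data rows are colon-separated channels of comma-separated values,
    with the class token as the final colon field. Class labels are
    mapped to 1..c preserving the order declared in ``@classLabel``.
    """
    path = Path(path)
    problem_name = path.stem
    declared_dims: int | None = None
    class_tokens: list[str] = []
    instances: list[np.ndarray] = []
    labels: list[int] = []
    in_data = False

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not in_data and line.startswith("@"):
                tag, _, rest = line.partition(" ")
                tag = tag.lower()
                rest = rest.strip()
                if tag == "@problemname":
                    problem_name = rest or problem_name
                elif tag == "@univariate":
                    if rest.lower() == "true":
                        declared_dims = 1
                elif tag == "@dimensions":
                    try:
                        declared_dims = int(rest)
                    except ValueError:
                        raise ParseError(f"bad @dimensions value {rest!r}", lineno)
                elif tag == "@classlabel":
                    parts = rest.split()
                    if not parts or parts[0].lower() != "true":
                        raise ParseError("@classLabel must be 'true <tokens...>'",
                                         lineno)
                    class_tokens = parts[1:]
                    if not class_tokens:
                        raise ParseError("@classLabel lists no class tokens", lineno)
                elif tag == "@data":
                    in_data = True
                # other tags tolerated
                continue
            if not in_data:
                raise ParseError(f"unexpected content before @data: {line!r}", lineno)
            fields = line.split(":")
            if len(fields) < 2:
                raise ParseError("data row needs at least one channel and a label",
                                 lineno)
            token = fields[-1].strip()
            if class_tokens:
                if token not in class_tokens:
                    raise ParseError(f"unknown class token {token!r}", lineno)
            else:
                if token not in class_tokens:
                    class_tokens.append(token)
            label = class_tokens.index(token) + 1
            channels = []
            for ch in fields[:-1]:
                try:
                    vals = np.array([float(v) for v in ch.split(",")],
                                    dtype=np.float64)
                except ValueError:
                    raise ParseError(f"cannot parse channel values {ch!r}", lineno)
                channels.append(vals)
            if declared_dims is not None and len(channels) != declared_dims:
                raise ParseError(
                    f"row has {len(channels)} channels, header declares "
                    f"{declared_dims}", lineno)
            hs = {c.size for c in channels}
            if len(hs) != 1:
                raise ParseError("channels of one instance must share a length",
                                 lineno)
            instances.append(np.vstack(channels))
            labels.append(label)

    if not instances:
        raise ParseError("file contains no data rows")
    # drop declared-but-unused trailing classes so labels span 1..c
    used = sorted(set(labels))
    remap = {old: new + 1 for new, old in enumerate(used)}
    labels = [remap[y] for y in labels]
    class_names = [class_tokens[old - 1] for old in used]
    return TimeSeriesDataset(instances=instances, labels=np.array(labels),
                             class_names=class_names, name=problem_name)


def write_ts(ds: TimeSeriesDataset, path) -> None:
    """Write a dataset in the UCR ``.ts`` dialect (17 significant digits).

    Inverse of :func:`read_ts` up to float formatting.
    """
    if ds.n_instances == 0:  # unreachable via the container, kept for safety
        raise DatasetError("cannot write an empty dataset")
    path = Path(path)
    lines = [f"@problemName {ds.name}"]
    if ds.n_channels == 1:
        lines.append("@univariate true")
    else:
        lines.append(f"@dimensions {ds.n_channels}")
    lines.append(f"@equalLength {'true' if ds.equal_length else 'false'}")
    lines.append("@classLabel true " + " ".join(ds.class_names))
    lines.append("@data")
    for x, y in zip(ds.instances, ds.labels):
        chans = [",".join(format(v, ".17g") for v in ch) for ch in x]
        lines.append(":".join(chans) + ":" + ds.class_names[int(y) - 1])
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------
# long CSV (instance, channel, time, value, label)
# ---------------------------------------------------------------------

def read_csv_long(path) -> TimeSeriesDataset:
    """Read the secondary long-CSV format with columns
    ``instance, channel, time, value, label``."""
    df = pd.read_csv(path)
    required = {"instance", "channel", "time", "value", "label"}
    if not required.issubset(df.columns):
        raise ParseError(f"long CSV needs columns {sorted(required)}")
    instances, labels, class_tokens = [], [], []
    for iid, grp in df.groupby("instance", sort=True):
        token = str(grp["label"].iloc[0])
        if token not in class_tokens:
            class_tokens.append(token)
        labels.append(class_tokens.index(token) + 1)
        chans = []
        for _, cg in grp.groupby("channel", sort=True):
            chans.append(cg.sort_values("time")["value"].to_numpy(dtype=np.float64))
        instances.append(np.vstack(chans))
    return TimeSeriesDataset(instances=instances, labels=np.array(labels),
                             class_names=class_tokens,
                             name=Path(path).stem)


def write_csv_long(ds: TimeSeriesDataset, path) -> None:
    recs = []
    for i, (x, y) in enumerate(zip(ds.instances, ds.labels)):
        for j in range(x.shape[0]):
            for t in range(x.shape[1]):
                recs.append((i, j, t, x[j, t], ds.class_names[int(y) - 1]))
    pd.DataFrame(recs, columns=["instance", "channel", "time", "value",
                                "label"]).to_csv(path, index=False)


# ---------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------

def resample_split(
    ds: TimeSeriesDataset,
    train_fraction: float,
    seed: int,
    stratified: bool = True,
) -> tuple[TimeSeriesDataset, TimeSeriesDataset]:
    """Seeded random train/test partition.

    Stratified (default): each class is split so that its train count is
    ``round(train_fraction * n_class)`` clipped to leave at least one
    instance on each side, keeping proportions within +-1 instance.
    """
    if not 0.0 < train_fraction < 1.0:
        raise DatasetError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: list[int] = []
    test_ids: list[int] = []
    if stratified:
        for cls in range(1, ds.n_classes + 1):
            ids = np.flatnonzero(ds.labels == cls)
            if ids.size < 2:
                raise DatasetError(
                    f"class {cls} has {ids.size} instance(s); stratified "
                    "splitting needs at least 2")
            perm = rng.permutation(ids)
            n_train = int(round(train_fraction * ids.size))
            n_train = min(max(n_train, 1), ids.size - 1)
            train_ids.extend(perm[:n_train].tolist())
            test_ids.extend(perm[n_train:].tolist())
    else:
        if ds.n_instances < 2:
            raise DatasetError("need at least 2 instances to split")
        perm = rng.permutation(ds.n_instances)
        n_train = int(round(train_fraction * ds.n_instances))
        n_train = min(max(n_train, 1), ds.n_instances - 1)
        train_ids = perm[:n_train].tolist()
        test_ids = perm[n_train:].tolist()
    train_ids.sort()
    test_ids.sort()
    return (ds.subset(train_ids, name=f"{ds.name}-train"),
            ds.subset(test_ids, name=f"{ds.name}-test"))
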