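"""Experiment orchestration, significance testing and the counting cost
model.

Two protocols are provided. The *noise sweep* holds one seeded
train/test split fixed and, at each integer noise multiplier, redraws
Gaussian noise per repetition, then trains and evaluates the raw,
single-scale (LLT) and multiscale (ALT) representations with the
built-in KNN; repetition r of every representation sees identical noise
(paired design). The *repeated benchmark* draws R seeded stratified
train/test resamples and evaluates raw vs ALT per repetition, again
paired, recording validation accuracy (cross-validated over a small
deterministic k grid), test accuracy and wall time (reported, never
asserted).

Significance: per dataset a two-sided paired Wilcoxon signed-rank test
over repetitions (zeros dropped; exact null for n <= 25 without tied
|differences|, normal approximation with continuity correction
otherwise), then Holm step-down correction across datasets.

The cost model counts, exactly, the windows w_i = floor((h_i - r)/k)+1
per LT instance, the dictionary sizes N^(j), the inference rows o, the
training operation count ~ sum_i m * sum_(r,l,k) w_i (l^2 + l^3), the
inference count sum_j sum_(r,l,k) o * l * N^(j) and the stored scalars
sum l * N^(j), with the bounds L_max and W_max.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

from .baselines import KNNClassifier, evaluate_accuracy, raw_features
from .datasets import TimeSeriesDataset, resample_split
from .errors import ConfigurationError, DatasetError
from .laws import LTSplitConfig, split_law_training
from .schedule import Schedule, ScheduleTriplet, count_row_embeddings
from .synthetic import SyntheticSpec, add_noise, generate_recurrence_dataset
from .transform import ALTModel, PoolingSpec

__all__ = ["NoiseSweepConfig", "BenchmarkConfig", "ExperimentResult",
           "CostReport", "run_noise_sweep", "run_repeated_benchmark",
           "wilcoxon_holm", "estimate_costs", "derive_seed"]


def derive_seed(master: int, *parts) -> int:
    """Deterministic child seed < 2^31 from a master seed and context."""
    h = np.uint64(1469598103934665603)  # FNV-1a over the context tuple
    for part in (master, *parts):
        for b in str(part).encode("utf-8"):
            h = np.uint64((int(h) ^ b) * 1099511628211 % (1 << 64))
    return int(h % (1 << 31))


@dataclass
class ExperimentResult:
    """Long-format records plus a per-cell summary table."""

    records: pd.DataFrame
    config: object = None

    def summary(self, by=("representation", "classifier", "noise")) -> pd.DataFrame:
        by = [b for b in by if b in self.records.columns]
        g = self.records.groupby(list(by))["test_accuracy"]
        out = g.agg(mean="mean", sd="std", n="count").reset_index()
        out["ci95_half"] = 1.96 * out["sd"].fillna(0.0) / np.sqrt(out["n"])
        return out


@dataclass
class NoiseSweepConfig:
    """Noise-robustness protocol configuration.

    ``dataset`` may be a :class:`TimeSeriesDataset` or a
    :class:`SyntheticSpec` (regenerated per run from its seed). The same
    split is reused across repetitions; noise is redrawn per repetition
    and level, identically for every representation.
    """

    dataset: object = None
    schedule: Schedule = None
    llt_triplet: ScheduleTriplet = None
    specs: list = field(default_factory=lambda: [PoolingSpec()])
    lt_config: LTSplitConfig = field(default_factory=LTSplitConfig)
    multipliers: tuple = tuple(range(21))
    repetitions: int = 30
    train_fraction: float = 0.5
    knn_k: int = 1
    master_seed: int = 0
    noise_on: str = "both"  # train | test | both
    representations: tuple = ("raw", "llt", "alt")

    def validate(self) -> None:
        if self.dataset is None:
            raise ConfigurationError("noise sweep needs a dataset or spec")
        if self.schedule is None:
            raise ConfigurationError("noise sweep needs a schedule")
        if any(m < 0 for m in self.multipliers):
            raise ConfigurationError("noise multipliers must be >= 0")
        if self.repetitions < 1:
            raise ConfigurationError("repetitions must be >= 1")
        if self.noise_on not in ("train", "test", "both"):
            raise ConfigurationError(f"invalid noise_on={self.noise_on!r}")
        unknown = set(self.representations) - {"raw", "llt", "alt"}
        if unknown:
            raise ConfigurationError(f"unknown representations {sorted(unknown)}")
        if "llt" in self.representations and self.llt_triplet is None and \
                len(self.schedule) != 1:
            raise ConfigurationError(
                "llt baseline needs llt_triplet when the schedule has "
                "several triplets")


def _resolve_dataset(obj) -> TimeSeriesDataset:
    if isinstance(obj, SyntheticSpec):
        return generate_recurrence_dataset(obj)
    if isinstance(obj, TimeSeriesDataset):
        return obj
    raise ConfigurationError(f"cannot interpret dataset object {type(obj)}")


def _fit_eval(train_feats, test_feats, k: int) -> float:
    clf = KNNClassifier(k=k).fit(train_feats.values, train_feats.labels)
    return evaluate_accuracy(clf.predict(test_feats.values), test_feats.labels)


def run_noise_sweep(config: NoiseSweepConfig) -> ExperimentResult:
    """Noise grid x representation x repetition, paired by seed."""
    config.validate()
    ds = _resolve_dataset(config.dataset)
    split_seed = derive_seed(config.master_seed, ds.name, "split")
    train0, test0 = resample_split(ds, config.train_fraction, split_seed)
    llt_trip = config.llt_triplet or config.schedule[0]
    records = []
    for rep in range(config.repetitions):
        for level in config.multipliers:
            noise_seed = derive_seed(config.master_seed, ds.name, "noise",
                                     rep, level)
            train = (add_noise(train0, level, noise_seed)
                     if config.noise_on in ("train", "both") else train0)
            test = (add_noise(test0, level, noise_seed + 1)
                    if config.noise_on in ("test", "both") else test0)
            feats = {}
            if "raw" in config.representations:
                feats["raw"] = (raw_features(train), raw_features(test))
            if "llt" in config.representations:
                m = ALTModel.fit(train, Schedule([llt_trip]), config.specs,
                                 config.lt_config)
                tr = train if config.lt_config.rho == 1.0 else \
                    train.subset(m.clf_ids)
                feats["llt"] = (m.transform(tr), m.transform(test))
            if "alt" in config.representations:
                m = ALTModel.fit(train, config.schedule, config.specs,
                                 config.lt_config)
                tr = train if config.lt_config.rho == 1.0 else \
                    train.subset(m.clf_ids)
                feats["alt"] = (m.transform(tr), m.transform(test))
            for rep_name, (ftr, fte) in feats.items():
                acc = _fit_eval(ftr, fte, config.knn_k)
                records.append({
                    "dataset": ds.name, "representation": rep_name,
                    "classifier": f"knn{config.knn_k}", "repetition": rep,
                    "noise": level, "test_accuracy": acc})
    return ExperimentResult(records=pd.DataFrame(records), config=config)


@dataclass
class BenchmarkConfig:
    """Repeated-resampling protocol configuration."""

    dataset: object = None
    schedule: Schedule = None
    specs: list = field(default_factory=lambda: [PoolingSpec()])
    lt_config: LTSplitConfig = field(default_factory=LTSplitConfig)
    repetitions: int = 30
    train_fraction: float = 0.5
    knn_grid: tuple = (1, 3, 5)
    cv_folds: int = 5
    master_seed: int = 0
    representations: tuple = ("raw", "alt")

    def validate(self) -> None:
        if self.dataset is None or self.schedule is None:
            raise ConfigurationError("benchmark needs a dataset and a schedule")
        if self.repetitions < 1:
            raise ConfigurationError("repetitions must be >= 1")
        if not self.knn_grid:
            raise ConfigurationError("knn_grid must be non-empty")


def _cv_select_k(X, y, grid, folds, seed) -> tuple[int, float]:
    """Pick k from a small deterministic grid by stratified CV accuracy."""
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y)
    n_per_class = np.bincount(y)[1:]
    folds = int(min(folds, n_per_class.min()))
    if folds < 2:
        # too few instances per class to cross-validate: use smallest k
        return int(grid[0]), float("nan")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_k, best_acc = int(grid[0]), -1.0
    for k in grid:
        accs = []
        for tr, va in skf.split(X, y):
            if k > len(tr):
                accs.append(0.0)
                continue
            clf = KNNClassifier(k=k).fit(X[tr], y[tr])
            accs.append(evaluate_accuracy(clf.predict(X[va]), y[va]))
        acc = float(np.mean(accs))
        if acc > best_acc:  # grid order breaks ties (smallest k first)
            best_k, best_acc = int(k), acc
    return best_k, best_acc


def run_repeated_benchmark(config: BenchmarkConfig) -> ExperimentResult:
    """R seeded resamples; raw and multiscale features share each split."""
    config.validate()
    ds = _resolve_dataset(config.dataset)
    records = []
    for rep in range(config.repetitions):
        split_seed = derive_seed(config.master_seed, ds.name, "resample", rep)
        train, test = resample_split(ds, config.train_fraction, split_seed)
        for rep_name in config.representations:
            t0 = time.perf_counter()
            if rep_name == "raw":
                ftr, fte = raw_features(train), raw_features(test)
            elif rep_name == "alt":
                m = ALTModel.fit(train, config.schedule, config.specs,
                                 config.lt_config)
                tr = train if config.lt_config.rho == 1.0 else \
                    train.subset(m.clf_ids)
                ftr, fte = m.transform(tr), m.transform(test)
            else:
                raise ConfigurationError(f"unknown representation {rep_name!r}")
            k, val_acc = _cv_select_k(ftr.values, ftr.labels, config.knn_grid,
                                      config.cv_folds,
                                      derive_seed(config.master_seed, "cv", rep))
            acc = _fit_eval(ftr, fte, k)
            records.append({
                "dataset": ds.name, "representation": rep_name,
                "classifier": f"knn{k}", "repetition": rep,
                "validation_accuracy": val_acc, "test_accuracy": acc,
                "wall_time_s": time.perf_counter() - t0})
    return ExperimentResult(records=pd.DataFrame(records), config=config)


def wilcoxon_holm(paired: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Paired signed-rank tests per dataset with Holm correction.

    ``paired`` maps a dataset name to a pair of equal-length accuracy
    arrays (A, B). Zero differences are dropped; if all differences are
    zero the p-value is 1 and nothing is rejected. Returns a table with
    the signed-rank statistic, raw and Holm-adjusted p-values and the
    rejection flag at level ``alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    rows = []
    for name, (a, b) in paired.items():
        a = np.asarray(a, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        if a.shape != b.shape or a.ndim != 1 or a.size == 0:
            raise DatasetError(
                f"dataset {name!r}: paired samples must be equal-length 1-D")
        d = a - b
        nz = d[d != 0.0]
        if nz.size == 0:
            rows.append({"dataset": name, "n_used": 0, "statistic": 0.0,
                         "p_value": 1.0})
            continue
        ranks_tied = (np.unique(np.abs(nz)).size < nz.size)
        method = "exact" if (nz.size <= 25 and not ranks_tied) else "approx"
        res = wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                       correction=(method == "approx"), method=method)
        rows.append({"dataset": name, "n_used": int(nz.size),
                     "statistic": float(res.statistic),
                     "p_value": float(res.pvalue)})
    table = pd.DataFrame(rows)
    reject, p_holm, _, _ = multipletests(table["p_value"], alpha=alpha,
                                         method="holm")
    table["p_holm"] = p_holm
    table["reject"] = reject
    return table


# ---------------------------------------------------------------------
# counting cost model
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class CostEntry:
    channel: int
    triplet: ScheduleTriplet
    windows_per_instance: tuple  # w_i over LT instances
    N_laws: int
    o_inference: int  # rows for a length-H query (H = min training length)
    stored_scalars: int


@dataclass(frozen=True)
class CostReport:
    """Exact operation/memory counts for a schedule on a dataset."""

    entries: tuple
    N_laws_total: int
    training_ops: int  # sum_i m sum_(r,l,k) w_i (l^2 + l^3)
    inference_ops: int  # sum_j sum_(r,l,k) o l N^(j), for one query
    stored_scalars_total: int  # sum l N^(j)
    L_max: int
    W_max: int
    n_lt_instances: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "channel": e.channel, "r": e.triplet.r, "l": e.triplet.l,
            "k": e.triplet.k, "N_laws": e.N_laws, "o": e.o_inference,
            "stored_scalars": e.stored_scalars,
            "total_windows": sum(e.windows_per_instance),
        } for e in self.entries])


def estimate_costs(schedule: Schedule, ds: TimeSeriesDataset,
                   lt_cfg: LTSplitConfig | None = None,
                   lt_ids=None, query_length: int | None = None) -> CostReport:
    """Count windows, laws, operations and stored scalars exactly.

    ``lt_ids`` overrides the LT split; otherwise it is derived from
    ``lt_cfg`` (default config if omitted). ``query_length`` sets H for
    the inference row count (default: the shortest training length).
    """
    if lt_ids is None:
        lt_ids, _ = split_law_training(ds, lt_cfg or LTSplitConfig())
    lt_ids = np.asarray(lt_ids, dtype=np.intp)
    lengths = ds.lengths[lt_ids]
    if schedule.max_r > lengths.min():
        raise DatasetError(
            f"max window length r={schedule.max_r} exceeds the shortest "
            f"LT instance (h={lengths.min()})")
    H = int(query_length if query_length is not None else ds.min_length)
    m = ds.n_channels
    entries = []
    training_ops = 0
    inference_ops = 0
    for trip in schedule:
        w = tuple(int((h - trip.r) // trip.k + 1) for h in lengths)
        N = sum(w)
        o = count_row_embeddings(H, trip)
        training_ops += m * sum(w) * (trip.l**2 + trip.l**3)
        for j in range(m):
            entries.append(CostEntry(
                channel=j, triplet=trip, windows_per_instance=w, N_laws=N,
                o_inference=o, stored_scalars=trip.l * N))
            inference_ops += o * trip.l * N
    N_total = sum(e.N_laws for e in entries)
    return CostReport(
        entries=tuple(entries),
        N_laws_total=N_total,
        training_ops=int(training_ops),
        inference_ops=int(inference_ops),
        stored_scalars_total=sum(e.stored_scalars for e in entries),
        L_max=max(t.l for t in schedule),
        W_max=max(max(e.windows_per_instance) for e in entries),
        n_lt_instances=int(lt_ids.size),
    )
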