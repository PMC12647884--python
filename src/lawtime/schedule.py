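"""Window schedules and delay embeddings.

A *schedule* is an ordered set of ``(r, l, k)`` triplets: window length
``r``, embedding dimension ``l`` and stride ``k``. Each triplet must
satisfy the structural constraint

    r = s * (2l - 2) + 1,   s a positive integer,

so that a window of length ``r`` contributes exactly ``2l - 1`` evenly
spaced samples with spacing ``s = (r - 1) / (2l - 2)``. From one window
starting at ``t`` we build the symmetric l x l delay (Hankel-type)
embedding ``S[p, q] = x[t + (p + q) * s]`` (0-based ``p, q``); at
inference time a series of length ``H`` is unrolled into
``o = floor((H - (l-1)s - 1) / k) + 1`` strided rows of length ``l``.

Indexing convention: the public API is 0-based (a start index ``t``
addresses ``x[t]``); the classical 1-based formulation maps onto it by
subtracting one from start and sample indices. Counting formulas are
identical in both conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .errors import ScheduleError, WindowError

__all__ = [
    "ScheduleTriplet",
    "Schedule",
    "SymmetricEmbedding",
    "RowEmbeddingMatrix",
    "validate_triplet",
    "enumerate_window_starts",
    "count_windows",
    "build_embedding_matrix",
    "count_row_embeddings",
    "build_row_embeddings",
]


@dataclass(frozen=True)
class ScheduleTriplet:
    """A validated (r, l, k) triplet with its derived spacing ``s``.

    Use :func:`validate_triplet` to construct; the constructor itself
    re-checks the invariants so an invalid triplet cannot exist.
    """

    r: int
    l: int
    k: int
    s: int = field(init=False)

    def __post_init__(self) -> None:
        for name in ("r", "l", "k"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ScheduleError(f"{name} must be a positive integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.l < 2:
            raise ScheduleError(f"embedding dimension l must be >= 2, got {self.l}")
        if self.k < 1:
            raise ScheduleError(f"stride k must be >= 1, got {self.k}")
        if self.r < 3:
            raise ScheduleError(f"window length r must be >= 3, got {self.r}")
        num, den = self.r - 1, 2 * self.l - 2
        if num % den != 0:
            raise ScheduleError(
                f"(r, l, k)=({self.r}, {self.l}, {self.k}): spacing "
                f"(r-1)/(2l-2) = {num}/{den} is not a positive integer"
            )
        s = num // den
        if s < 1:
            raise ScheduleError(f"derived spacing s={s} must be >= 1")
        object.__setattr__(self, "s", s)

    @property
    def span(self) -> int:
        """Number of samples covered by one symmetric window (equals r)."""
        return (2 * self.l - 2) * self.s + 1

    def row_span(self) -> int:
        """Samples covered by one inference row embedding: (l-1)s + 1."""
        return (self.l - 1) * self.s + 1

    def __str__(self) -> str:  # used in feature names and error messages
        return f"(r={self.r}, l={self.l}, k={self.k}, s={self.s})"


def validate_triplet(r: int, l: int, k: int) -> ScheduleTriplet:
    """Validate (r, l, k) and return the triplet with derived spacing.

    Raises :class:`ScheduleError` when ``(r - 1)`` is not a positive
    multiple of ``2l - 2``, when ``l < 2`` or when ``k < 1``.
    """
    return ScheduleTriplet(r, l, k)


@dataclass(frozen=True)
class Schedule:
    """Ordered, duplicate-free sequence of triplets (the set R).

    Order is significant: it fixes the feature-column layout.
    """

    triplets: tuple[ScheduleTriplet, ...]

    def __init__(self, triplets: Iterable[ScheduleTriplet | tuple[int, int, int]]):
        tl = tuple(
            t if isinstance(t, ScheduleTriplet) else validate_triplet(*t)
            for t in triplets
        )
        if not tl:
            raise ScheduleError("schedule must contain at least one triplet")
        seen: set[tuple[int, int, int]] = set()
        for t in tl:
            key = (t.r, t.l, t.k)
            if key in seen:
                raise ScheduleError(f"duplicate triplet {t} in schedule")
            seen.add(key)
        object.__setattr__(self, "triplets", tl)

    def __len__(self) -> int:
        return len(self.triplets)

    def __iter__(self) -> Iterator[ScheduleTriplet]:
        return iter(self.triplets)

    def __getitem__(self, i: int) -> ScheduleTriplet:
        return self.triplets[i]

    @property
    def max_r(self) -> int:
        return max(t.r for t in self.triplets)

    @classmethod
    def parse(cls, text: str) -> "Schedule":
        """Parse ``"(r,l,k);(r,l,k);..."`` (whitespace tolerated)."""
        parts = [p.strip() for p in text.split(";") if p.strip()]
        triplets = []
        for p in parts:
            body = p.strip("() ")
            try:
                r, l, k = (int(v) for v in body.split(","))
            except ValueError as exc:
                raise ScheduleError(f"cannot parse triplet {p!r}") from exc
            triplets.append(validate_triplet(r, l, k))
        return cls(triplets)


@dataclass(frozen=True)
class SymmetricEmbedding:
    """l x l symmetric delay embedding of one window, with its source."""

    values: np.ndarray
    source: tuple  # (instance_id, channel, start, triplet)


@dataclass(frozen=True)
class RowEmbeddingMatrix:
    """o x l matrix of strided inference rows for one channel/triplet."""

    values: np.ndarray
    channel: int
    triplet: ScheduleTriplet

    @property
    def o(self) -> int:
        return self.values.shape[0]


def count_windows(h: int, trip: ScheduleTriplet) -> int:
    """Number of symmetric training windows in a length-``h`` series."""
    if h < trip.r:
        raise WindowError(
            f"series of length {h} is too short for window length r={trip.r}"
        )
    return (h - trip.r) // trip.k + 1


def enumerate_window_starts(h: int, trip: ScheduleTriplet) -> np.ndarray:
    """0-based start indices t = 0, k, 2k, ... with t + r <= h.

    Count equals ``floor((h - r)/k) + 1``; raises :class:`WindowError`
    when the series is shorter than ``r``.
    """
    n = count_windows(h, trip)
    return np.arange(n, dtype=np.intp) * trip.k


def _as_series(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise WindowError(f"expected a 1-D sample sequence, got shape {arr.shape}")
    return arr


def build_embedding_matrix(
    channel_series, t: int, trip: ScheduleTriplet, source: tuple = ()
) -> SymmetricEmbedding:
    """Symmetric embedding of the window starting at 0-based index ``t``.

    ``S[p, q] = x[t + (p + q) * s]``; symmetry is bit-exact because both
    entries read the same input sample. Non-finite samples inside the
    window are a hard error (the eigensolver contract requires finite,
    symmetric input).
    """
    x = _as_series(channel_series)
    l, s = trip.l, trip.s
    last = t + (2 * l - 2) * s
    if t < 0 or last >= x.size:
        raise WindowError(
            f"window at t={t} with span {trip.span} exceeds series length {x.size}"
        )
    window = x[t : last + 1 : s]  # the 2l-1 strided samples
    if not np.all(np.isfinite(window)):
        raise WindowError(f"non-finite sample inside window at t={t}")
    idx = np.arange(l)
    S = window[idx[:, None] + idx[None, :]]
    return SymmetricEmbedding(values=S, source=source or (None, None, t, trip))


def count_row_embeddings(H: int, trip: ScheduleTriplet) -> int:
    """Number of inference rows: ``o = floor((H - (l-1)s - 1)/k) + 1``."""
    span = trip.row_span()
    if H < span:
        raise WindowError(
            f"series of length {H} is too short for row span (l-1)s+1={span}"
        )
    return (H - span) // trip.k + 1


def build_row_embeddings(
    channel_series, trip: ScheduleTriplet, channel: int = 0
) -> RowEmbeddingMatrix:
    """o x l matrix with ``A[u, q] = z[u*k + q*s]`` (0-based)."""
    z = _as_series(channel_series)
    o = count_row_embeddings(z.size, trip)
    if not np.all(np.isfinite(z)):
        raise WindowError("non-finite sample in series")
    rows = np.arange(o)[:, None] * trip.k + np.arange(trip.l)[None, :] * trip.s
    return RowEmbeddingMatrix(values=z[rows], channel=channel, triplet=trip)
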