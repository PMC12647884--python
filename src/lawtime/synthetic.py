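"""Synthetic labeled series with class-specific linear-recurrence structure.

Classes are defined either by a sinusoid (angular frequency ``omega``,
uniformly random phase per instance and channel) or by a stable AR
process. A noiseless sinusoid satisfies the fixed order-2 recurrence
``x[t+1] = 2 cos(omega s) x[t] - x[t-1]`` at every spacing ``s``, so any
same-channel delay embedding with ``l >= 3`` has rank <= 2 and a
null-space law exists — the separability mechanism the transformation
exploits. Random phases ensure classes are not separable by alignment
alone, which keeps raw-sample baselines honest.

Additive noise follows the integer-multiplier protocol: level ``M``
adds i.i.d. ``Normal(0, M^2)`` to every sample (M = 0 adds nothing,
bit-exactly); the standard grid is M in {0..20}. Non-integer multipliers
are accepted (the noise scale is a continuous parameter).

The default two-class spec (:func:`two_class_sinusoid_spec`) uses
omega = 0.3 vs 0.9, one channel, h = 100, 20 instances per class and
amplitude 10, so the unit-variance multiplier grid spans near-noiseless
(M=1, SNR ~ 7) to noise-dominated (M=20) conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .datasets import TimeSeriesDataset
from .errors import SpecError

__all__ = ["SinusoidClass", "MultiToneClass", "ARClass", "SyntheticSpec",
           "generate_recurrence_dataset", "add_noise",
           "two_class_sinusoid_spec", "noise_robustness_spec"]


@dataclass(frozen=True)
class SinusoidClass:
    """Sinusoid class: ``amplitude * sin(omega * t + phase)`` with phase
    ~ U(0, 2*pi) per instance and channel. ``channel_omega_offsets``
    (length m) shifts the frequency per channel."""

    omega: float
    amplitude: float = 10.0
    channel_omega_offsets: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.omega < np.pi:
            raise SpecError(f"omega must be in (0, pi), got {self.omega}")

    def sample(self, rng: np.random.Generator, m: int, h: int) -> np.ndarray:
        offsets = self.channel_omega_offsets or (0.0,) * m
        if len(offsets) != m:
            raise SpecError(
                f"channel_omega_offsets has length {len(offsets)}, expected {m}")
        t = np.arange(h)
        chans = []
        for j in range(m):
            w = self.omega + offsets[j]
            if not 0.0 < w < np.pi:
                raise SpecError(f"channel {j} frequency {w} out of (0, pi)")
            phase = rng.uniform(0.0, 2.0 * np.pi)
            chans.append(self.amplitude * np.sin(w * t + phase))
        return np.vstack(chans)


@dataclass(frozen=True)
class MultiToneClass:
    """Sum of sinusoid components, each with an independent uniform
    random phase per instance and channel.

    A noiseless p-tone signal satisfies a fixed order-2p linear
    recurrence, so embeddings with ``l >= 2p + 1`` admit an exact
    annihilating law. Components shared between classes act as nuisance
    structure: their random phase dominates raw sample-space distances
    while contributing nothing to cross-class law responses (the
    annihilating filter's roots remove shared tones exactly).
    """

    components: tuple[tuple[float, float], ...]  # (omega, amplitude)

    def __post_init__(self) -> None:
        if not self.components:
            raise SpecError("MultiToneClass needs at least one component")
        for w, a in self.components:
            if not 0.0 < w < np.pi:
                raise SpecError(f"omega must be in (0, pi), got {w}")
            if a <= 0:
                raise SpecError(f"amplitude must be positive, got {a}")

    @property
    def recurrence_order(self) -> int:
        return 2 * len(self.components)

    def sample(self, rng: np.random.Generator, m: int, h: int) -> np.ndarray:
        t = np.arange(h)
        chans = []
        for _ in range(m):
            x = np.zeros(h)
            for w, a in self.components:
                x += a * np.sin(w * t + rng.uniform(0.0, 2.0 * np.pi))
            chans.append(x)
        return np.vstack(chans)


@dataclass(frozen=True)
class ARClass:
    """Stable AR(p) class: x[t] = sum_a coef[a] x[t-1-a] + eps_t."""

    coefficients: tuple[float, ...]
    innovation_sd: float = 1.0
    channel_coefficient_scale: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self._check_stable(self.coefficients)
        if self.innovation_sd <= 0:
            raise SpecError("innovation_sd must be positive")

    @staticmethod
    def _check_stable(coefs: Sequence[float]) -> None:
        # characteristic polynomial z^p - a1 z^{p-1} - ... - ap
        poly = np.r_[1.0, -np.asarray(coefs, dtype=float)]
        roots = np.roots(poly)
        if roots.size and np.max(np.abs(roots)) >= 1.0 - 1e-9:
            raise SpecError(f"AR coefficients {tuple(coefs)} are not stable")

    def sample(self, rng: np.random.Generator, m: int, h: int) -> np.ndarray:
        scales = self.channel_coefficient_scale or (1.0,) * m
        if len(scales) != m:
            raise SpecError("channel_coefficient_scale length mismatch")
        burn = 5 * len(self.coefficients) + 50
        chans = []
        for j in range(m):
            coefs = np.asarray(self.coefficients) * scales[j]
            self._check_stable(coefs)
            eps = rng.normal(0.0, self.innovation_sd, size=h + burn)
            x = lfilter([1.0], np.r_[1.0, -coefs], eps)
            chans.append(x[burn:])
        return np.vstack(chans)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a labeled recurrence dataset."""

    classes: tuple = ()
    n_channels: int = 1
    length: int | tuple[int, int] = 100
    instances_per_class: int = 20
    seed: int = 0
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.classes:
            raise SpecError("spec needs at least one class generator")
        if self.instances_per_class < 1:
            raise SpecError("instances_per_class must be >= 1")
        if self.n_channels < 1:
            raise SpecError("n_channels must be >= 1")
        if isinstance(self.length, tuple):
            lo, hi = self.length
            if not 1 <= lo <= hi:
                raise SpecError(f"invalid length range {self.length}")
        elif self.length < 1:
            raise SpecError("length must be >= 1")


def two_class_sinusoid_spec(seed: int = 0, h: int = 100,
                            instances_per_class: int = 20,
                            amplitude: float = 10.0) -> SyntheticSpec:
    """The default study conditions: omega = 0.3 vs 0.9, one channel."""
    return SyntheticSpec(
        classes=(SinusoidClass(0.3, amplitude), SinusoidClass(0.9, amplitude)),
        n_channels=1, length=h, instances_per_class=instances_per_class,
        seed=seed, class_names=("slow", "fast"))


def noise_robustness_spec(seed: int = 0, h: int = 100,
                          instances_per_class: int = 20) -> SyntheticSpec:
    """Surrogate for the noise-robustness protocol: the two class tones
    (omega = 0.3 vs 0.9, amplitude 10) are masked by a stronger shared
    nuisance tone (omega = 1.7, amplitude 20) with random phase.

    The nuisance dominates raw sample-space distances — as dominant
    common rhythms do in real sensor data — while the classes still
    differ by the order-4 recurrence each satisfies, so law-based
    features (l >= 5) separate them exactly in the noiseless limit.
    """
    return SyntheticSpec(
        classes=(MultiToneClass(((0.3, 10.0), (1.7, 20.0))),
                 MultiToneClass(((0.9, 10.0), (1.7, 20.0)))),
        n_channels=1, length=h, instances_per_class=instances_per_class,
        seed=seed, class_names=("slow", "fast"))


def generate_recurrence_dataset(spec: SyntheticSpec) -> TimeSeriesDataset:
    """Seeded, reproducible dataset; instances grouped by class."""
    rng = np.random.default_rng(spec.seed)
    instances, labels = [], []
    for ci, gen in enumerate(spec.classes, start=1):
        for _ in range(spec.instances_per_class):
            if isinstance(spec.length, tuple):
                h = int(rng.integers(spec.length[0], spec.length[1] + 1))
            else:
                h = int(spec.length)
            instances.append(gen.sample(rng, spec.n_channels, h))
            labels.append(ci)
    names = list(spec.class_names) if spec.class_names else [
        f"class{i}" for i in range(1, len(spec.classes) + 1)]
    if len(names) != len(spec.classes):
        raise SpecError("class_names must match the number of classes")
    return TimeSeriesDataset(instances=instances, labels=np.array(labels),
                             class_names=names, name="synthetic")


def add_noise(ds: TimeSeriesDataset, multiplier: float,
              seed: int) -> TimeSeriesDataset:
    """Add i.i.d. ``Normal(0, multiplier^2)`` to every sample.

    ``multiplier = 0`` returns values identical to the input. Noise is
    independent across samples, channels and instances, and fully
    determined by ``seed``.
    """
    if multiplier < 0:
        raise SpecError(f"noise multiplier must be >= 0, got {multiplier}")
    out = ds.copy()
    if multiplier == 0:
        return out
    rng = np.random.default_rng(seed)
    out.instances = [x + multiplier * rng.standard_normal(x.shape)
                     for x in out.instances]
    return out
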