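import numpy as np
import pytest

from lawtime import (Schedule, SinusoidClass, SyntheticSpec,
                     generate_recurrence_dataset, validate_triplet)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_valid_triplet(rng, l_max=8, s_max=4, k_max=4):
    """Draw (r, l, k) satisfying r = s(2l-2)+1."""
    l = int(rng.integers(2, l_max + 1))
    s = int(rng.integers(1, s_max + 1))
    k = int(rng.integers(1, k_max + 1))
    return validate_triplet(s * (2 * l - 2) + 1, l, k)


def random_dataset(rng, n_classes=2, per_class=4, m=1, h=40):
    """Small random-walk dataset with per-class drift (arbitrary labels)."""
    instances, labels = [], []
    for cls in range(1, n_classes + 1):
        for _ in range(per_class):
            steps = rng.normal(0.1 * cls, 1.0, size=(m, h))
            instances.append(np.cumsum(steps, axis=1))
            labels.append(cls)
    from lawtime import TimeSeriesDataset

    return TimeSeriesDataset(instances=instances, labels=np.array(labels))


@pytest.fixture
def two_sine_dataset():
    """Noiseless two-class sinusoid dataset (order-2 recurrence classes)."""
    spec = SyntheticSpec(
        classes=(SinusoidClass(0.3, 10.0), SinusoidClass(0.9, 10.0)),
        n_channels=1, length=100, instances_per_class=20, seed=7,
        class_names=("slow", "fast"))
    return generate_recurrence_dataset(spec)


@pytest.fixture
def small_schedule():
    return Schedule([(5, 3, 1)])
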