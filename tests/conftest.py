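"""Shared fixtures: small hand-built datasets and generator helpers."""

from __future__ import annotations

import numpy as np
import pytest

from rgife import Dataset, LearnerConfig, SyntheticSpec, generate_dataset


@pytest.fixture
def separable_1d() -> Dataset:
    """One attribute; class A at {1,2,3}, class B at {10,11,12}."""
    return Dataset(
        attribute_names=["g1"],
        sample_ids=[f"s{i}" for i in range(6)],
        values=np.array([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]]),
        class_labels=["A", "A", "A", "B", "B", "B"],
    )


@pytest.fixture
def separable_8() -> Dataset:
    """One attribute, classes at 0s and 100s, 4 + 4 samples."""
    return Dataset(
        attribute_names=["g1"],
        sample_ids=[f"s{i}" for i in range(8)],
        values=np.array([[0.0]] * 4 + [[100.0]] * 4),
        class_labels=["low"] * 4 + ["high"] * 4,
    )


@pytest.fixture
def constant_4() -> Dataset:
    """4 samples, 2 balanced classes, every attribute value identical."""
    return Dataset(
        attribute_names=["g1", "g2"],
        sample_ids=["s0", "s1", "s2", "s3"],
        values=np.full((4, 2), 7.0),
        class_labels=["A", "B", "A", "B"],
    )


@pytest.fixture
def three_attr() -> Dataset:
    """3 attributes, distinct per-column values, for projection tests."""
    return Dataset(
        attribute_names=["f1", "f2", "f3"],
        sample_ids=["s0", "s1", "s2", "s3"],
        values=np.arange(12, dtype=float).reshape(4, 3),
        class_labels=["A", "B", "A", "B"],
    )


@pytest.fixture
def learner_config() -> LearnerConfig:
    return LearnerConfig(seed=0)


def make_synthetic(**kwargs):
    """Convenience wrapper: SyntheticSpec defaults scaled for unit tests."""
    params = dict(
        n_samples=20, n_attributes=30, n_informative=2,
        n_classes=2, effect_size=3.0, seed=0,
    )
    params.update(kwargs)
    return generate_dataset(SyntheticSpec(**params))


def random_small_dataset(rng: np.random.Generator) -> Dataset:
    """A random labelled table with <=2 attributes and <=12 samples.

    Half the time values are drawn from a small integer grid so ties and
    repeated values are exercised.  Always contains two classes.
    """
    n = int(rng.integers(4, 13))
    p = int(rng.integers(1, 3))
    if rng.random() < 0.5:
        values = rng.integers(0, 6, size=(n, p)).astype(float)
    else:
        values = np.round(rng.normal(size=(n, p)), 2)
    labels = ["A" if rng.random() < 0.5 else "B" for _ in range(n)]
    if len(set(labels)) < 2:  # force both classes present
        labels[0], labels[1] = "A", "B"
    return Dataset(
        attribute_names=[f"f{j}" for j in range(p)],
        sample_ids=[str(i) for i in range(n)],
        values=values,
        class_labels=labels,
    )
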