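"""Class-structured synthetic omics tables with known ground truth.

Generates sample x attribute matrices shaped like small omics studies
(tens of samples, tens to tens of thousands of attributes): most attributes
are class-independent noise, a chosen few are *informative* — their
class-conditional means are separated by a configurable multiple of the
within-class standard deviation.  An optional sparsity fraction zeroes
entries to mimic the presence/absence character of label-free proteomics
quantitation, and a log-normal option gives abundance-like skew.

Attribute names carry no hint of informativeness; the ground-truth set is
returned separately so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    effect_size is the separation between adjacent class means on each
    informative attribute, in units of the within-class SD (Gaussian
    model).  sparsity is the fraction of matrix entries forced to exactly
    zero.  class_proportions defaults to balanced classes.
    """

    n_samples: int
    n_attributes: int
    n_informative: int
    n_classes: int = 2
    effect_size: float = 2.5
    sparsity: float = 0.0
    class_proportions: tuple[float, ...] | None = None
    seed: int = 0
    distribution: str = "gaussian"  # or "lognormal"
    pairwise_interaction: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_attributes < 1:
            raise ValueError("n_attributes must be >= 1")
        if not (0 <= self.n_informative <= self.n_attributes):
            raise ValueError("n_informative must be in [0, n_attributes]")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0.0 <= self.sparsity < 1.0):
            raise ValueError("sparsity must be in [0, 1)")
        if self.distribution not in ("gaussian", "lognormal"):
            raise ValueError("distribution must be 'gaussian' or 'lognormal'")
        if self.class_proportions is not None:
            props = tuple(float(p) for p in self.class_proportions)
            if len(props) != self.n_classes:
                raise ValueError("class_proportions length must equal n_classes")
            if any(p <= 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
                raise ValueError("class_proportions must be positive and sum to 1")
            object.__setattr__(self, "class_proportions", props)
        if self.pairwise_interaction:
            if self.n_classes != 2:
                raise ValueError("pairwise_interaction supports 2 classes only")
            if self.n_informative % 2:
                raise ValueError("pairwise_interaction needs an even n_informative")


def _class_counts(spec: SyntheticSpec) -> np.ndarray:
    """Deterministic per-class sample counts (largest-remainder rounding)."""
    props = spec.class_proportions or tuple(
        [1.0 / spec.n_classes] * spec.n_classes
    )
    raw = np.array(props) * spec.n_samples
    counts = np.floor(raw).astype(int)
    remainder = spec.n_samples - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    if (counts == 0).any():
        raise ValueError("every class needs at least one sample")
    return counts


def generate_dataset(spec: SyntheticSpec) -> tuple[Dataset, frozenset[str]]:
    """Draw one dataset from the spec; returns (dataset, informative names).

    Noise attributes are i.i.d. standard normal regardless of class; each
    informative attribute adds ``effect_size`` x a seed-chosen permutation
    of class ranks to the class members, so adjacent class means differ by
    ``effect_size`` within-class SDs.  Sparsity then zeroes a seed-chosen
    subset of entries.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_samples, spec.n_attributes, spec.n_classes

    counts = _class_counts(spec)
    codes = np.repeat(np.arange(k), counts)
    rng.shuffle(codes)

    values = rng.standard_normal((n, p))
    informative_idx = np.sort(rng.choice(p, size=spec.n_informative, replace=False))

    if spec.pairwise_interaction:
        # XOR-style paired signal: neither attribute separates the classes
        # alone, the pair does — exercises multi-condition rules.
        half = spec.effect_size
        pos_class = codes == 1
        for a, b in zip(informative_idx[0::2], informative_idx[1::2]):
            flips = rng.integers(0, 2, size=n).astype(bool)
            sign = np.where(flips, 1.0, -1.0)
            values[pos_class, a] += half * sign[pos_class]
            values[pos_class, b] += half * sign[pos_class]
            values[~pos_class, a] += half * sign[~pos_class]
            values[~pos_class, b] -= half * sign[~pos_class]
    else:
        for j in informative_idx:
            offsets = rng.permutation(k) * spec.effect_size
            values[:, j] += offsets[codes]

    if spec.distribution == "lognormal":
        values = np.exp(values)

    if spec.sparsity > 0:
        n_zero = int(round(spec.sparsity * n * p))
        flat = rng.choice(n * p, size=n_zero, replace=False)
        values.flat[flat] = 0.0

    width = max(4, len(str(p - 1)))
    attribute_names = [f"attr{j:0{width}d}" for j in range(p)]
    sample_ids = [f"s{i:03d}" for i in range(n)]
    class_labels = [f"class{c}" for c in codes]
    dataset = Dataset(attribute_names, sample_ids, values, class_labels)
    truth = frozenset(attribute_names[j] for j in informative_idx)
    return dataset, truth
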