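"""Leave-one-out cross-validation and sensitivity/specificity metrics.

Each of the n samples is held out once, a decision list is trained on the
other n-1, and the held-out prediction is accumulated into a confusion
matrix.  Two scalars summarise a run: TPR (sensitivity) — the proportion of
samples correctly classified, i.e. overall accuracy, whose percentage form
is the classification accuracy — and TNR (specificity) — the unweighted
mean over classes of the one-vs-rest proportion of negatives correctly
classified.  The fold models are returned alongside the metrics: the
elimination engine reads its attribute relevance ranking out of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import Dataset
from .rules import LearnerConfig, RuleSet, induce_ruleset


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K count matrix; entry (i, j) = true class i predicted as class j."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def correct(self) -> int:
        return int(np.trace(self.counts))


def confusion_metrics(
    confusion: ConfusionMatrix,
) -> tuple[float, float, list[dict]]:
    """TPR, TNR and per-class sensitivity/specificity from a confusion matrix.

    TPR is micro — trace over total, equal to overall accuracy.  TNR is the
    unweighted macro mean of one-vs-rest specificities ``TN_c / (TN_c +
    FP_c)``.  A class with zero negatives contributes specificity 1.0 by
    convention (flagged in its per-class record); likewise a class with zero
    positives contributes sensitivity 1.0.
    """
    m = confusion.counts
    total = confusion.total
    if total < 1:
        raise ValueError("empty confusion matrix")
    tpr = confusion.correct / total

    per_class: list[dict] = []
    specs: list[float] = []
    for i, cls in enumerate(confusion.classes):
        tp = int(m[i, i])
        fn = int(m[i].sum()) - tp
        fp = int(m[:, i].sum()) - tp
        tn = total - tp - fn - fp
        positives = tp + fn
        negatives = tn + fp
        sens = tp / positives if positives else 1.0
        spec = tn / negatives if negatives else 1.0
        specs.append(spec)
        per_class.append(
            {
                "class": cls,
                "tp": tp,
                "fn": fn,
                "fp": fp,
                "tn": tn,
                "sensitivity": sens,
                "specificity": spec,
                "degenerate": positives == 0 or negatives == 0,
            }
        )
    tnr = float(np.mean(specs))
    return tpr, tnr, per_class


@dataclass(frozen=True)
class EvaluationResult:
    """A LOOCV outcome: confusion matrix, scalar metrics and fold models."""

    confusion: ConfusionMatrix
    correct_count: int
    tpr: float
    tnr: float
    per_class: tuple[dict, ...]
    fold_models: tuple[RuleSet, ...]

    @property
    def n_samples(self) -> int:
        return self.confusion.total


def loocv_evaluate(dataset: Dataset, config: LearnerConfig) -> EvaluationResult:
    """Evaluate the decision-list learner on a dataset by leave-one-out CV.

    One fold per sample, processed in sample order; the learner is
    deterministic and order-independent, so the confusion matrix does not
    depend on sample ordering.  Requires at least two samples and two
    classes.
    """
    n = dataset.n_samples
    if n < 2:
        raise ValueError("LOOCV needs at least 2 samples")
    if dataset.n_classes < 2:
        raise ValueError("LOOCV needs at least 2 classes")

    classes = tuple(dataset.class_set)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    models: list[RuleSet] = []
    all_rows = np.arange(n)
    for i in range(n):
        train = dataset.subset_rows(all_rows[all_rows != i])
        model = induce_ruleset(train, config)
        predicted = model.classify(dataset.sample_mapping(i))
        counts[index[dataset.class_labels[i]], index[predicted]] += 1
        models.append(model)

    confusion = ConfusionMatrix(classes, counts)
    tpr, tnr, per_class = confusion_metrics(confusion)
    return EvaluationResult(
        confusion=confusion,
        correct_count=confusion.correct,
        tpr=tpr,
        tnr=tnr,
        per_class=tuple(per_class),
        fold_models=tuple(models),
    )
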