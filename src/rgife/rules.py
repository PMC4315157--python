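"""A deterministic decision-list learner over attribute-threshold rules.

Models are ordered lists of conjunctive rules — ``IF geneX > t AND geneY < u
THEN classC`` — closed by a default class, evaluated first-match.  This is
the rule format rule-based omics classifiers expose to the biologist: every
attribute that appears in a condition is directly readable off the model.

Induction is greedy separate-and-conquer: :func:`grow_rule` adds one
condition at a time, each chosen to maximise the m-estimate precision of the
best class among the covered samples; :func:`induce_ruleset` repeatedly grows
a rule on the not-yet-covered samples and removes what it covers.  Every tie
is broken deterministically (score, then coverage, then attribute order, then
``>`` before ``<``, then lower threshold), so identical data and
configuration always yield structurally identical models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dataset import Dataset, format_number

GT = ">"
LT = "<"


@dataclass(frozen=True)
class Condition:
    """A strict single-attribute threshold test, ``attribute > t`` or ``< t``."""

    attribute: str
    operator: str  # GT or LT
    threshold: float

    def __post_init__(self) -> None:
        if self.operator not in (GT, LT):
            raise ValueError(f"operator must be {GT!r} or {LT!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def matches(self, value: float) -> bool:
        if self.operator == GT:
            return value > self.threshold
        return value < self.threshold


@dataclass(frozen=True)
class Rule:
    """A conjunction of conditions predicting one class.

    A sample matches iff *all* conditions hold; a zero-condition rule
    matches every sample.
    """

    conditions: tuple[Condition, ...]
    predicted_class: str

    def matches(self, sample: Mapping[str, float]) -> bool:
        for cond in self.conditions:
            if cond.attribute not in sample:
                raise KeyError(
                    f"sample is missing attribute {cond.attribute!r} "
                    "referenced by the model"
                )
            if not cond.matches(sample[cond.attribute]):
                return False
        return True

    def coverage_mask(self, dataset: Dataset) -> np.ndarray:
        """Boolean mask of dataset rows whose values satisfy all conditions."""
        mask = np.ones(dataset.n_samples, dtype=bool)
        for cond in self.conditions:
            col = dataset.attribute_column(cond.attribute)
            mask &= (col > cond.threshold) if cond.operator == GT else (col < cond.threshold)
        return mask


@dataclass(frozen=True)
class RuleSet:
    """An ordered decision list with a default class (first match fires)."""

    rules: tuple[Rule, ...]
    default_class: str
    class_set: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.default_class not in self.class_set:
            raise ValueError("default_class must belong to class_set")

    def classify(self, sample: Mapping[str, float]) -> str:
        for rule in self.rules:
            if rule.matches(sample):
                return rule.predicted_class
        return self.default_class

    def referenced_attributes(self) -> set[str]:
        return {c.attribute for r in self.rules for c in r.conditions}


@dataclass(frozen=True)
class LearnerConfig:
    """Hyperparameters of the decision-list learner.

    max_conditions_per_rule : longest allowed conjunction (default 3).
    min_rule_coverage : a grown rule must cover at least this many of the
        remaining samples to be kept (default 2; suppresses singleton rules).
    purity_stop : stop refining a rule once the covered samples reach this
        class purity (default 1.0 — fully pure).
    m_estimate : Laplace-style smoothing mass for rule precision, with the
        class prior taken from the current view (default 1.0).
    seed : recorded in run summaries; the learner itself is deterministic.
    """

    max_conditions_per_rule: int = 3
    min_rule_coverage: int = 2
    purity_stop: float = 1.0
    m_estimate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_conditions_per_rule < 1:
            raise ValueError("max_conditions_per_rule must be >= 1")
        if self.min_rule_coverage < 1:
            raise ValueError("min_rule_coverage must be >= 1")
        if not (0.0 < self.purity_stop <= 1.0):
            raise ValueError("purity_stop must be in (0, 1]")
        if self.m_estimate < 0:
            raise ValueError("m_estimate must be >= 0")


def candidate_thresholds(values: Sequence[float] | np.ndarray) -> list[float]:
    """Midpoints between consecutive distinct sorted values.

    Empty when all values are equal — no split exists.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    distinct = np.unique(arr)
    return list((distinct[1:] + distinct[:-1]) / 2.0)


@dataclass(frozen=True)
class _Candidate:
    score: float
    coverage: int
    attr_index: int
    operator: str
    threshold: float

    def key(self) -> tuple:
        # larger is better: score desc, coverage desc, attribute asc,
        # GT before LT, threshold asc
        return (
            self.score,
            self.coverage,
            -self.attr_index,
            1 if self.operator == GT else 0,
            -self.threshold,
        )


def _m_estimate_score(counts: np.ndarray, coverage, prior: np.ndarray, m: float):
    """Best-class m-estimate precision; broadcasts over candidate axes."""
    cov = np.asarray(coverage, dtype=float)[..., None]
    return np.max((counts + m * prior) / (cov + m), axis=-1)


def _best_condition(
    X: np.ndarray, y: np.ndarray, prior: np.ndarray, m: float
) -> _Candidate | None:
    """The single best threshold condition over a covered submatrix.

    Scores every (attribute, midpoint, operator) candidate in one vectorised
    pass: columns are sorted once, class counts on each side of every cut
    come from cumulative one-hot sums.
    """
    mc, p = X.shape
    if mc < 2:
        return None
    k = len(prior)
    order = np.argsort(X, axis=0, kind="stable")
    S = np.take_along_axis(X, order, axis=0)
    Ys = y[order]  # (mc, p) class code of each sorted row
    onehot = np.zeros((mc, p, k))
    np.put_along_axis(onehot, Ys[:, :, None], 1.0, axis=2)
    csum = np.cumsum(onehot, axis=0)  # counts among the first i+1 sorted rows
    totals = csum[-1]  # (p, k)

    valid = S[1:] > S[:-1]  # a cut exists only between distinct values
    if not valid.any():
        return None
    thresholds = (S[1:] + S[:-1]) / 2.0  # (mc-1, p)
    below = csum[:-1]  # class counts strictly below each cut
    above = totals[None, :, :] - below
    cov_below = np.arange(1, mc, dtype=float)[:, None]  # (mc-1, 1)
    cov_above = mc - cov_below

    neg = -np.inf
    s_gt = np.where(valid, _m_estimate_score(above, np.broadcast_to(cov_above, valid.shape), prior, m), neg)
    s_lt = np.where(valid, _m_estimate_score(below, np.broadcast_to(cov_below, valid.shape), prior, m), neg)

    best_score = max(s_gt.max(), s_lt.max())
    if best_score == neg:
        return None
    best: _Candidate | None = None
    for op, scores, covs in ((GT, s_gt, cov_above), (LT, s_lt, cov_below)):
        hit = scores == best_score
        if not hit.any():
            continue
        cov_grid = np.broadcast_to(covs, scores.shape)
        cov_star = cov_grid[hit].max()
        hit = hit & (cov_grid == cov_star)
        cols = np.flatnonzero(hit.any(axis=0))
        j = int(cols[0])
        t = float(thresholds[:, j][hit[:, j]].min())
        cand = _Candidate(float(best_score), int(cov_star), j, op, t)
        if best is None or cand.key() > best.key():
            best = cand
    return best


def _majority_class(codes: np.ndarray, k: int) -> int:
    """Majority class code; ties go to the earlier first-appearance code."""
    counts = np.bincount(codes, minlength=k)
    return int(np.argmax(counts))


def grow_rule(view: Dataset, config: LearnerConfig) -> Rule:
    """Grow one conjunctive rule on the given view of training samples.

    Greedily appends the condition maximising the m-estimate precision of
    the best class among the covered samples; stops at class purity
    ``purity_stop``, at ``max_conditions_per_rule`` conditions, or when no
    condition strictly improves the score.  The predicted class is the
    majority class of the covered samples.  A single-class view yields a
    zero-condition rule predicting that class.
    """
    if view.n_samples < 1:
        raise ValueError("cannot grow a rule on an empty view")
    classes = view.class_set
    k = len(classes)
    y = view.class_codes()
    if k == 1:
        return Rule((), classes[0])

    counts = np.bincount(y, minlength=k).astype(float)
    prior = counts / counts.sum()
    m = config.m_estimate

    mask = np.ones(view.n_samples, dtype=bool)
    conditions: list[Condition] = []
    cov_counts = counts.copy()
    current_score = float(
        np.max((cov_counts + m * prior) / (cov_counts.sum() + m))
    )
    while len(conditions) < config.max_conditions_per_rule:
        covered_y = y[mask]
        purity = np.bincount(covered_y, minlength=k).max() / covered_y.size
        if purity >= config.purity_stop:
            break
        cand = _best_condition(view.values[mask], covered_y, prior, m)
        if cand is None or cand.score <= current_score:
            break
        attr = view.attribute_names[cand.attr_index]
        conditions.append(Condition(attr, cand.operator, cand.threshold))
        col = view.values[:, cand.attr_index]
        mask &= (col > cand.threshold) if cand.operator == GT else (col < cand.threshold)
        current_score = cand.score

    covered_y = y[mask]
    pred = _majority_class(covered_y, k) if covered_y.size else _majority_class(y, k)
    return Rule(tuple(conditions), classes[pred])


def induce_ruleset(train: Dataset, config: LearnerConfig) -> RuleSet:
    """Learn an ordered decision list by separate-and-conquer.

    Rules are grown on the not-yet-covered samples and appended while they
    cover at least ``min_rule_coverage`` remaining samples; induction stops
    when the remaining samples are single-class or exhausted.  The default
    class is the majority of the uncovered remainder (whole-training-set
    majority when nothing remains).  Deterministic given data and config.
    """
    if train.n_samples < 1:
        raise ValueError("cannot induce a rule set on an empty dataset")
    classes = tuple(train.class_set)
    k = len(classes)
    y_all = train.class_codes()

    remaining = np.ones(train.n_samples, dtype=bool)
    rules: list[Rule] = []
    while remaining.any():
        rem_codes = y_all[remaining]
        if np.unique(rem_codes).size <= 1:
            break
        view = train.subset_rows(remaining)
        rule = grow_rule(view, config)
        covered_rem = rule.coverage_mask(view)
        if int(covered_rem.sum()) < config.min_rule_coverage:
            break
        rules.append(rule)
        rem_idx = np.flatnonzero(remaining)
        remaining[rem_idx[covered_rem]] = False

    if remaining.any():
        default = classes[_majority_class(y_all[remaining], k)]
    else:
        default = classes[_majority_class(y_all, k)]
    return RuleSet(tuple(rules), default, classes)


def classify(model: RuleSet, sample: Mapping[str, float]) -> str:
    """Label a sample with the first matching rule, else the default class."""
    return model.classify(sample)


def render_rule(rule: Rule) -> str:
    if not rule.conditions:
        return f"IF TRUE THEN {rule.predicted_class}"
    conj = " AND ".join(
        f"{c.attribute} {c.operator} {format_number(c.threshold)}"
        for c in rule.conditions
    )
    return f"IF {conj} THEN {rule.predicted_class}"


def render_ruleset(model: RuleSet) -> str:
    """One rule per line, closed by the default class."""
    lines = [render_rule(r) for r in model.rules]
    lines.append(f"DEFAULT {model.default_class}")
    return "\n".join(lines)
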