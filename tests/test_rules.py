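"""Decision-list learner: greedy growth vs exhaustive oracles, semantics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rgife import (
    Condition,
    Dataset,
    LearnerConfig,
    Rule,
    RuleSet,
    candidate_thresholds,
    classify,
    grow_rule,
    induce_ruleset,
    render_ruleset,
)

from conftest import random_small_dataset


# ---------------------------------------------------------------------------
# independent oracles (plain loops, no shared code with the implementation)
# ---------------------------------------------------------------------------

def _view_prior(view):
    classes = view.class_set
    y = [classes.index(c) for c in view.class_labels]
    counts = [y.count(i) for i in range(len(classes))]
    prior = [c / len(y) for c in counts]
    return classes, y, prior


def brute_force_condition(view: Dataset, m: float):
    """Exhaustive argmax over every (attribute, midpoint, operator) candidate.

    Same score and tie-break order as the learner, coded independently with
    plain loops.  Returns (key, (attr_idx, op, thr)) or None.
    """
    classes, y, prior = _view_prior(view)
    best = None
    for j in range(view.n_attributes):
        col = [view.values[i, j] for i in range(view.n_samples)]
        for t in candidate_thresholds(col):
            for op_rank, op in ((1, ">"), (0, "<")):
                covered = [
                    i for i, v in enumerate(col)
                    if (v > t if op == ">" else v < t)
                ]
                if not covered:
                    continue
                score = max(
                    (sum(1 for i in covered if y[i] == k) + m * prior[k])
                    / (len(covered) + m)
                    for k in range(len(classes))
                )
                key = (score, len(covered), -j, op_rank, -t)
                if best is None or key > best[0]:
                    best = (key, (j, op, t))
    return best


def brute_force_pair_score(view: Dataset, m: float):
    """Best m-estimate score over every conjunction of <=2 conditions."""
    classes, y, prior = _view_prior(view)
    conds = []
    for j in range(view.n_attributes):
        col = view.values[:, j]
        for t in candidate_thresholds(col):
            for op in (">", "<"):
                conds.append((j, op, t))

    def covered_by(pair):
        rows = []
        for i in range(view.n_samples):
            ok = True
            for j, op, t in pair:
                v = view.values[i, j]
                if not (v > t if op == ">" else v < t):
                    ok = False
                    break
            if ok:
                rows.append(i)
        return rows

    best_score, best_cover = -1.0, None
    for a in range(len(conds)):
        for b in range(a, len(conds)):
            covered = covered_by([conds[a], conds[b]])
            if not covered:
                continue
            score = max(
                (sum(1 for i in covered if y[i] == k) + m * prior[k])
                / (len(covered) + m)
                for k in range(len(classes))
            )
            if score > best_score:
                best_score, best_cover = score, covered
    return best_score, best_cover


# ---------------------------------------------------------------------------
# candidate thresholds
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "values,expected",
    [
        ([1, 2, 4], [1.5, 3.0]),
        ([5, 5, 5], []),
        ([0, 100], [50.0]),
        ([2, 1, 2, 4, 1], [1.5, 3.0]),  # duplicates collapse
    ],
)
def test_candidate_thresholds(values, expected):
    assert candidate_thresholds(values) == expected


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.integers(-50, 50), min_size=1, max_size=20))
def test_thresholds_sit_between_distinct_values(values):
    thresholds = candidate_thresholds(values)
    distinct = sorted(set(values))
    assert len(thresholds) == len(distinct) - 1
    for lo, hi, t in zip(distinct, distinct[1:], thresholds):
        assert lo < t < hi


# ---------------------------------------------------------------------------
# grow_rule
# ---------------------------------------------------------------------------

class TestGrowRule:
    def test_separable_classes_split_at_midpoint(self, separable_1d, learner_config):
        rule = grow_rule(separable_1d, learner_config)
        assert len(rule.conditions) == 1
        cond = rule.conditions[0]
        assert cond.attribute == "g1"
        assert cond.threshold == 6.5
        # matches the exhaustive argmax under the same scoring
        _, (j, op, t) = brute_force_condition(separable_1d, learner_config.m_estimate)
        assert (separable_1d.attribute_names[j], op, t) == (
            cond.attribute, cond.operator, cond.threshold
        )

    def test_single_class_view_gives_empty_rule(self, learner_config):
        view = Dataset(["g1"], ["s0", "s1"], [[1.0], [2.0]], ["OA", "OA"])
        rule = grow_rule(view, learner_config)
        assert rule.conditions == ()
        assert rule.predicted_class == "OA"

    def test_greedy_first_condition_matches_exhaustive_on_100_random_sets(self):
        """Greedy == brute force over all candidate conditions (oracle)."""
        config = LearnerConfig(seed=0)
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(100):
            view = random_small_dataset(rng)
            rule = grow_rule(view, config)
            oracle = brute_force_condition(view, config.m_estimate)
            if rule.conditions:
                assert oracle is not None
                j, op, t = oracle[1]
                cond = rule.conditions[0]
                assert cond.attribute == view.attribute_names[j]
                assert cond.operator == op
                assert cond.threshold == t
                checked += 1
            else:
                # greedy declined every condition: none may beat the
                # zero-condition baseline score
                classes, y, prior = _view_prior(view)
                m = config.m_estimate
                counts = [y.count(k) for k in range(len(classes))]
                baseline = max(
                    (counts[k] + m * prior[k]) / (len(y) + m)
                    for k in range(len(classes))
                )
                if oracle is not None:
                    assert oracle[0][0] <= baseline
        assert checked >= 50  # the comparison must actually exercise growth

    def test_two_condition_growth_matches_exhaustive_pair(self):
        """Straddled counterexamples force a conjunction; greedy's covered
        set attains the exhaustive best two-condition score."""
        # class A occupies the quadrant f1 > 5 and f2 < 3; one counterexample
        # on each side so no single threshold isolates A
        values = np.array(
            [
                [6.0, 1.0], [6.5, 2.0], [7.0, 1.3],
                [7.5, 2.2], [8.0, 0.9], [8.5, 1.8],  # A quadrant
                [1.0, 0.5],  # B: low f1, low f2
                [9.0, 4.0],  # B: high f1, high f2
            ]
        )
        view = Dataset(
            ["f1", "f2"], [str(i) for i in range(8)], values,
            ["A"] * 6 + ["B"] * 2,
        )
        config = LearnerConfig(seed=0)
        rule = grow_rule(view, config)
        assert rule.predicted_class == "A"
        assert len(rule.conditions) == 2
        covered = sorted(
            np.flatnonzero(rule.coverage_mask(view)).tolist()
        )
        assert covered == [0, 1, 2, 3, 4, 5]
        best_score, best_cover = brute_force_pair_score(view, config.m_estimate)
        assert sorted(best_cover) == covered

    def test_max_conditions_cap(self, learner_config):
        rng = np.random.default_rng(5)
        view = Dataset(
            [f"f{j}" for j in range(4)],
            [str(i) for i in range(16)],
            rng.normal(size=(16, 4)),
            ["A" if rng.random() < 0.5 else "B" for _ in range(16)],
        )
        rule = grow_rule(view, LearnerConfig(max_conditions_per_rule=1, seed=0))
        assert len(rule.conditions) <= 1

    def test_empty_view_rejected(self, learner_config):
        view = Dataset(["g1"], ["s0"], [[1.0]], ["A"])
        empty = view.subset_rows(np.array([], dtype=int))
        with pytest.raises(ValueError):
            grow_rule(empty, learner_config)


# ---------------------------------------------------------------------------
# induce_ruleset
# ---------------------------------------------------------------------------

class TestInduceRuleset:
    def test_single_class_dataset(self, learner_config):
        ds = Dataset(["g1"], ["s0", "s1"], [[1.0], [2.0]], ["OA", "OA"])
        model = induce_ruleset(ds, learner_config)
        assert model.rules == ()
        assert model.default_class == "OA"

    def test_separable_training_accuracy_is_one(self, separable_1d, learner_config):
        model = induce_ruleset(separable_1d, learner_config)
        for i in range(separable_1d.n_samples):
            assert (
                model.classify(separable_1d.sample_mapping(i))
                == separable_1d.class_labels[i]
            )

    def test_quadrant_fixture_classified_perfectly(self, learner_config):
        """Six quadrant samples vs six straddling counterexamples: the
        decision list peels the pure clusters then isolates the quadrant."""
        values = np.array(
            [
                [6.0, 1.0], [6.5, 2.0], [7.0, 1.3],
                [7.5, 2.2], [8.0, 0.9], [8.5, 1.8],   # A: f1>5 and f2<3
                [1.0, 1.5], [2.0, 0.7], [3.0, 1.1],   # B: low f1
                [9.0, 4.0], [9.5, 4.5], [7.2, 5.0],   # B: high f2
            ]
        )
        ds = Dataset(
            ["f1", "f2"], [str(i) for i in range(12)], values,
            ["A"] * 6 + ["B"] * 6,
        )
        model = induce_ruleset(ds, learner_config)
        for i in range(ds.n_samples):
            assert model.classify(ds.sample_mapping(i)) == ds.class_labels[i]

    def test_uncovered_count_strictly_decreases(self, learner_config):
        rng = np.random.default_rng(11)
        ds = Dataset(
            [f"f{j}" for j in range(3)],
            [str(i) for i in range(20)],
            rng.normal(size=(20, 3)),
            ["A" if i % 2 else "B" for i in range(20)],
        )
        model = induce_ruleset(ds, learner_config)
        remaining = np.ones(ds.n_samples, dtype=bool)
        for rule in model.rules:
            view = ds.subset_rows(remaining)
            covered = rule.coverage_mask(view)
            assert covered.sum() >= learner_config.min_rule_coverage
            idx = np.flatnonzero(remaining)
            remaining[idx[covered]] = False

    def test_identical_inputs_identical_models(self, separable_1d, learner_config):
        a = induce_ruleset(separable_1d, learner_config)
        b = induce_ruleset(separable_1d, learner_config)
        assert a == b


# ---------------------------------------------------------------------------
# classify and rendering
# ---------------------------------------------------------------------------

def _figure_style_model() -> RuleSet:
    rule = Rule((Condition("207211_at", ">", 100.0),), "OA")
    return RuleSet((rule,), "control", ("OA", "control"))


class TestClassify:
    def test_first_matching_rule_fires(self):
        model = _figure_style_model()
        assert classify(model, {"207211_at": 150.0}) == "OA"
        assert classify(model, {"207211_at": 50.0}) == "control"

    def test_empty_rule_list_returns_default(self):
        model = RuleSet((), "control", ("OA", "control"))
        assert classify(model, {"anything": 1.0}) == "control"

    def test_rule_order_decides_overlaps(self):
        r1 = Rule((Condition("g", ">", 0.0),), "A")
        r2 = Rule((Condition("g", ">", -1.0),), "B")
        model = RuleSet((r1, r2), "B", ("A", "B"))
        assert classify(model, {"g": 5.0}) == "A"

    def test_missing_attribute_value_rejected(self):
        model = _figure_style_model()
        with pytest.raises(KeyError, match="207211_at"):
            classify(model, {"other": 1.0})

    def test_totality_on_random_samples(self):
        model = _figure_style_model()
        rng = np.random.default_rng(1)
        for _ in range(50):
            label = classify(model, {"207211_at": float(rng.normal(100, 60))})
            assert label in model.class_set


class TestRendering:
    def test_threshold_rule_renders_in_figure_style(self):
        text = render_ruleset(_figure_style_model())
        assert "207211_at > 100" in text
        assert text.splitlines()[0].endswith("THEN OA")
        assert text.splitlines()[-1] == "DEFAULT control"

    def test_zero_condition_rule(self):
        model = RuleSet((Rule((), "A"),), "A", ("A", "B"))
        assert render_ruleset(model).splitlines()[0] == "IF TRUE THEN A"
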