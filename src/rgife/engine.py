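"""The rule-guided iterative feature elimination heuristic.

Plain backward elimination — drop one attribute, retrain, keep the drop if
accuracy survives — is hopeless on omics tables with tens of thousands of
attributes.  This engine makes it tractable with three changes:

* **guidance** — candidate attributes come from the bottom of a relevance
  ranking read out of the rule-set models, not from random choice;
* **blocks** — attributes are removed in blocks, starting at 25% of the
  attributes and shrinking to 25% of the previous size whenever all
  attributes have been tested at the current size or five consecutive
  trials have failed;
* **relaxed acceptance** — after five consecutive failures, a trial whose
  accuracy drop was worth at most one sample (``tolerance_samples``) may be
  accepted anyway before the block shrinks.

A trial removes a block, re-runs leave-one-out cross-validation on the rest,
and compares correct-classification *counts* (never rounded percentages)
against the reference.  Equal-or-better trials are accepted: the block is
gone for good, the reference moves, and the ranking is recomputed from the
accepted fold models.  The run ends once blocks are single attributes and
either every survivor has been tested or five consecutive trials each lost
more than the tolerance.

Everything is deterministic given the input data, configuration and seed;
the per-trial audit log suffices to replay the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

from .dataset import Dataset, project_attributes
from .evaluation import EvaluationResult, loocv_evaluate
from .ranking import AttributeRanking, rank_attributes
from .rules import LearnerConfig, RuleSet, induce_ruleset

ACCEPT = "ACCEPT"
ACCEPT_RELAXED = "ACCEPT_RELAXED"
REJECT = "REJECT"

FAIL = "FAIL"
FAIL_RESCUABLE = "FAIL_RESCUABLE"

EXHAUSTED = None  # sentinel returned by next_block


@dataclass(frozen=True)
class RGIFEConfig:
    """Engine parameters; the defaults are the heuristic's stated constants.

    initial_block_fraction : first block = this fraction of the attribute
        count (default 0.25).
    shrink_factor : each shrink multiplies the block size by this fraction
        (default 0.25).
    max_consecutive_failures : failed trials tolerated before a rescue
        check and block shrink (default 5).
    tolerance_samples : the largest accuracy drop, in correctly classified
        samples, that a relaxed acceptance may cost (default 1).
    reference : ``"previous"`` compares each trial with the last accepted
        model; ``"best"`` compares with the best correct-count seen so far.
    seed : threaded to the learner and recorded in outputs; the engine
        itself is deterministic.
    """

    initial_block_fraction: float = 0.25
    shrink_factor: float = 0.25
    max_consecutive_failures: int = 5
    tolerance_samples: int = 1
    reference: str = "previous"
    seed: int = 0
    learner: LearnerConfig = field(default_factory=LearnerConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.initial_block_fraction <= 1.0):
            raise ValueError("initial_block_fraction must be in (0, 1]")
        if not (0.0 < self.shrink_factor <= 1.0):
            raise ValueError("shrink_factor must be in (0, 1]")
        if self.max_consecutive_failures < 1:
            raise ValueError("max_consecutive_failures must be >= 1")
        if self.tolerance_samples < 0:
            raise ValueError("tolerance_samples must be >= 0")
        if self.reference not in ("previous", "best"):
            raise ValueError("reference must be 'previous' or 'best'")
        if self.learner.seed != self.seed:
            object.__setattr__(
                self, "learner", LearnerConfig(
                    max_conditions_per_rule=self.learner.max_conditions_per_rule,
                    min_rule_coverage=self.learner.min_rule_coverage,
                    purity_stop=self.learner.purity_stop,
                    m_estimate=self.learner.m_estimate,
                    seed=self.seed,
                )
            )


@dataclass(frozen=True)
class TrialRecord:
    """One audited elimination trial (or rescue event)."""

    iteration: int
    block_size: int
    block: tuple[str, ...]
    ref_correct: int
    trial_correct: int
    decision: str  # ACCEPT | ACCEPT_RELAXED | REJECT
    consecutive_failures: int
    n_attributes_after: int


@dataclass(frozen=True)
class RGIFEResult:
    """The outcome of a full elimination run."""

    initial_dataset: Dataset
    final_dataset: Dataset
    initial_evaluation: EvaluationResult
    final_evaluation: EvaluationResult
    trials: tuple[TrialRecord, ...]
    final_ranking: AttributeRanking
    final_model: RuleSet
    config: RGIFEConfig

    @property
    def accept_count(self) -> int:
        return sum(1 for t in self.trials if t.decision == ACCEPT)

    @property
    def relaxed_count(self) -> int:
        return sum(1 for t in self.trials if t.decision == ACCEPT_RELAXED)

    @property
    def reject_count(self) -> int:
        return sum(1 for t in self.trials if t.decision == REJECT)

    def removed_attributes(self) -> set[str]:
        return set(self.initial_dataset.attribute_names) - set(
            self.final_dataset.attribute_names
        )

    def summary_dict(self) -> dict:
        """A JSON-serialisable run summary (no timestamps — reproducible)."""
        cfg = asdict(self.config)
        return {
            "n_samples": self.initial_dataset.n_samples,
            "n_classes": self.initial_dataset.n_classes,
            "initial_attribute_count": self.initial_dataset.n_attributes,
            "final_attribute_count": self.final_dataset.n_attributes,
            "initial_correct_count": self.initial_evaluation.correct_count,
            "final_correct_count": self.final_evaluation.correct_count,
            "initial_tpr": self.initial_evaluation.tpr,
            "initial_tnr": self.initial_evaluation.tnr,
            "final_tpr": self.final_evaluation.tpr,
            "final_tnr": self.final_evaluation.tnr,
            "accept_count": self.accept_count,
            "accept_relaxed_count": self.relaxed_count,
            "reject_count": self.reject_count,
            "n_trials": len(self.trials),
            "final_attributes": list(self.final_dataset.attribute_names),
            "seed": self.config.seed,
            "config": cfg,
        }


# ---------------------------------------------------------------------------
# schedule primitives
# ---------------------------------------------------------------------------

def initial_block_size(n_attributes: int, fraction: float = 0.25) -> int:
    """First block size: ceil(fraction x n_attributes), never below 1."""
    if n_attributes < 1:
        raise ValueError("n_attributes must be >= 1")
    return max(1, math.ceil(fraction * n_attributes))


def shrink_block_size(current: int, factor: float = 0.25) -> int:
    """Next block size after a shrink: ceil(factor x current), floored at 1."""
    if current < 1:
        raise ValueError("current block size must be >= 1")
    return max(1, math.ceil(factor * current))


def next_block(
    ranking: AttributeRanking,
    tested: set[str],
    block_size: int,
) -> tuple[str, ...] | None:
    """The next candidate block: the lowest-ranked untested attributes.

    Walks the ranking bottom-up, collecting up to ``block_size`` untested
    attributes — fewer when fewer remain (partial blocks), and never all
    surviving attributes at once (at least one must always remain).
    Returns ``None`` (exhausted) when no testable block exists.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    untested = [a for a in ranking.attributes_bottom_up() if a not in tested]
    if not untested:
        return EXHAUSTED
    block = untested[: min(block_size, len(untested))]
    if len(block) == len(ranking):  # would empty the dataset
        block = block[:-1]  # spare the top-ranked attribute
    if not block:
        return EXHAUSTED
    return tuple(block)


def decide_trial(ref_correct: int, trial_correct: int, tolerance: int) -> str:
    """Classify a trial outcome by correct-classification counts.

    ACCEPT when the trial is equal or better than the reference;
    FAIL_RESCUABLE when it drops by at most ``tolerance`` samples (such a
    trial may be accepted later under the relaxed criterion); FAIL
    otherwise.
    """
    if trial_correct >= ref_correct:
        return ACCEPT
    if ref_correct - trial_correct <= tolerance:
        return FAIL_RESCUABLE
    return FAIL


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

@dataclass
class _Failure:
    outcome: str
    trial_correct: int
    block: tuple[str, ...]
    evaluation: EvaluationResult
    reduced: Dataset


def run_rgife(dataset: Dataset, config: RGIFEConfig | None = None) -> RGIFEResult:
    """Run the full iterative feature elimination heuristic on a dataset.

    Returns the reduced dataset together with the final LOOCV evaluation,
    the final ranking and model, and the complete trial log.  Fully
    deterministic given the dataset, configuration and seed.
    """
    if config is None:
        config = RGIFEConfig()
    if dataset.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if dataset.n_classes < 2:
        raise ValueError("need at least 2 classes")

    learner = config.learner
    current = dataset
    initial_eval = loocv_evaluate(current, learner)
    current_eval = initial_eval
    ref_correct = initial_eval.correct_count
    ranking = rank_attributes(
        initial_eval.fold_models, current.attribute_names, current
    )

    block_size = initial_block_size(
        current.n_attributes, config.initial_block_fraction
    )
    tested: set[str] = set()
    failures: list[_Failure] = []
    trials: list[TrialRecord] = []
    iteration = 0

    def log(block, trial_correct, decision, n_failures):
        nonlocal iteration
        iteration += 1
        trials.append(
            TrialRecord(
                iteration=iteration,
                block_size=block_size,
                block=tuple(block),
                ref_correct=ref_correct,
                trial_correct=trial_correct,
                decision=decision,
                consecutive_failures=n_failures,
                n_attributes_after=current.n_attributes,
            )
        )

    def accept(reduced, evaluation, new_ref):
        nonlocal current, current_eval, ref_correct, ranking, tested, failures
        current = reduced
        current_eval = evaluation
        ref_correct = new_ref
        ranking = rank_attributes(
            evaluation.fold_models, current.attribute_names, current
        )
        tested = set()
        failures = []

    while True:
        block = next_block(ranking, tested, block_size)
        if block is EXHAUSTED:
            if block_size == 1:
                break
            block_size = shrink_block_size(block_size, config.shrink_factor)
            tested = set()
            failures = []
            continue

        reduced = project_attributes(current, block)
        trial_eval = loocv_evaluate(reduced, learner)
        outcome = decide_trial(
            ref_correct, trial_eval.correct_count, config.tolerance_samples
        )

        if outcome == ACCEPT:
            new_ref = (
                trial_eval.correct_count
                if config.reference == "previous"
                else max(ref_correct, trial_eval.correct_count)
            )
            prev_ref = ref_correct
            accept(reduced, trial_eval, new_ref)
            # log with the pre-acceptance reference for an honest audit row
            iteration += 1
            trials.append(
                TrialRecord(
                    iteration=iteration,
                    block_size=block_size,
                    block=tuple(block),
                    ref_correct=prev_ref,
                    trial_correct=trial_eval.correct_count,
                    decision=ACCEPT,
                    consecutive_failures=0,
                    n_attributes_after=current.n_attributes,
                )
            )
            continue

        # failed trial: the block stays in the dataset, marked tested
        tested |= set(block)
        failures.append(
            _Failure(outcome, trial_eval.correct_count, block, trial_eval, reduced)
        )
        log(block, trial_eval.correct_count, REJECT, len(failures))

        if len(failures) < config.max_consecutive_failures:
            continue

        rescuable = [f for f in failures if f.outcome == FAIL_RESCUABLE]
        if rescuable:
            # relaxed acceptance: best trial_correct, earliest on ties
            best = max(rescuable, key=lambda f: f.trial_correct)
            new_ref = (
                best.trial_correct
                if config.reference == "previous"
                else ref_correct
            )
            prev_ref = ref_correct
            accept(best.reduced, best.evaluation, new_ref)
            iteration += 1
            trials.append(
                TrialRecord(
                    iteration=iteration,
                    block_size=block_size,
                    block=tuple(best.block),
                    ref_correct=prev_ref,
                    trial_correct=best.trial_correct,
                    decision=ACCEPT_RELAXED,
                    consecutive_failures=0,
                    n_attributes_after=current.n_attributes,
                )
            )
            continue

        # a full window of hard failures
        if block_size == 1:
            break
        block_size = shrink_block_size(block_size, config.shrink_factor)
        tested = set()
        failures = []

    final_model = induce_ruleset(current, learner)
    return RGIFEResult(
        initial_dataset=dataset,
        final_dataset=current,
        initial_evaluation=initial_eval,
        final_evaluation=current_eval,
        trials=tuple(trials),
        final_ranking=ranking,
        final_model=final_model,
        config=config,
    )
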