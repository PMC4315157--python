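"""Attribute relevance ranking extracted from rule-set models.

A rule-based model wears its feature usage on its sleeve: an attribute
matters to the extent that rules test it.  The ranking scores each
surviving attribute by the number of rules (summed over all LOOCV fold
models) that reference it in at least one condition; the elimination engine
then removes attributes from the *bottom* of this ranking first.

Ties are broken by the total training-set coverage of the rules containing
the attribute (higher coverage = more relevant), then by original attribute
order — so the ranking is a deterministic total order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .dataset import Dataset
from .rules import RuleSet


@dataclass(frozen=True)
class AttributeRanking:
    """Attributes ordered most- to least-relevant with usage scores.

    ``entries`` is a list of ``(attribute, usage_score)`` pairs sorted
    descending by relevance and covers the surviving attribute set exactly.
    """

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        names = [a for a, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("ranking must list each attribute exactly once")
        if any(s < 0 for _, s in self.entries):
            raise ValueError("usage scores must be non-negative")

    def attributes_top_down(self) -> list[str]:
        return [a for a, _ in self.entries]

    def attributes_bottom_up(self) -> list[str]:
        return [a for a, _ in reversed(self.entries)]

    def score(self, attribute: str) -> float:
        for a, s in self.entries:
            if a == attribute:
                return s
        raise KeyError(attribute)

    def __len__(self) -> int:
        return len(self.entries)


def rank_attributes(
    models: Iterable[RuleSet],
    attributes: Sequence[str],
    train: Dataset,
) -> AttributeRanking:
    """Rank surviving attributes by rule usage across fold models.

    ``usage_score(a)`` counts the rules, over all models, in which ``a``
    appears in at least one condition.  Attributes used by no rule score 0
    and sit at the bottom.  Raises if any rule references an attribute
    outside the surviving set.
    """
    models = list(models)
    if not models:
        raise ValueError("at least one model is required")
    if not attributes:
        raise ValueError("attribute list must be non-empty")
    surviving = set(attributes)

    usage = {a: 0 for a in attributes}
    coverage_weight = {a: 0.0 for a in attributes}
    for model in models:
        for rule in model.rules:
            attrs_in_rule = {c.attribute for c in rule.conditions}
            stray = attrs_in_rule - surviving
            if stray:
                raise ValueError(
                    f"rule references attributes outside the surviving set: "
                    f"{sorted(stray)}"
                )
            if not attrs_in_rule:
                continue
            cov = int(rule.coverage_mask(train).sum())
            for a in attrs_in_rule:
                usage[a] += 1
                coverage_weight[a] += cov

    order_index = {a: i for i, a in enumerate(attributes)}
    ordered = sorted(
        attributes,
        key=lambda a: (-usage[a], -coverage_weight[a], order_index[a]),
    )
    return AttributeRanking(tuple((a, float(usage[a])) for a in ordered))
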