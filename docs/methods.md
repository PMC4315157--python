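# Methods

## Problem setting

Given a labelled numeric table of `n` samples × `p` attributes (genes,
proteins; `p >> n` is typical), find a small attribute subset whose
cross-validated classification accuracy matches or exceeds that of the
full table. The package couples a rule-based classifier to a block-wise
backward-elimination loop; the surviving attributes are the candidate
biomarker panel.

## The base learner

The classifier is an ordered decision list of conjunctive threshold rules
with a default class, evaluated first-match. Induction is deterministic
greedy separate-and-conquer:

- `grow_rule` adds one condition at a time. Candidate conditions are
  `(attribute, > or <, t)` with `t` ranging over midpoints between
  consecutive distinct values of the currently covered samples. Each
  candidate is scored by the m-estimate precision of its best class,
  `(n_c + m·π_c) / (N + m)` with `m = 1` and prior `π_c` equal to the
  class frequency in the view; the m-estimate keeps one-sample rules from
  scoring 1.0. Growth stops at class purity 1.0 (`purity_stop`), at 3
  conditions (`max_conditions_per_rule`), or when no condition strictly
  improves the score.
- `induce_ruleset` grows rules on the not-yet-covered samples, appending a
  rule while it covers ≥ 2 remaining samples (`min_rule_coverage`);
  induction stops when the remainder is single-class or empty. The default
  class is the majority of the uncovered remainder (whole-set majority when
  nothing remains).

Every tie is broken in a fixed order — score, then coverage, then original
attribute order, then `>` before `<`, then lower threshold; majority-class
ties go to first-appearance order — so a (dataset, configuration) pair
always produces the same model on any platform. Strict inequalities with
midpoint thresholds make `<` vs `≤` immaterial on training data.

The learner sits behind a narrow interface (`induce_ruleset(Dataset) ->
RuleSet`), so any classifier that exposes rule-level attribute usage could
be substituted.

## Ranking

After each LOOCV evaluation, every surviving attribute is scored by the
number of rules, summed over the n fold models, in which it appears in at
least one condition. Ties are broken by the total training-set coverage of
the rules containing the attribute (higher = more relevant), then by
original attribute order. The ranking is recomputed from the fold models
of each *accepted* trial; rejected trials leave it unchanged — the
accepted model is the current best description of the data. Attributes
used by no rule score 0 and are eliminated first.

## The elimination engine

Parameters (defaults are the heuristic's standard constants):

| parameter | default | meaning |
|---|---|---|
| `initial_block_fraction` | 0.25 | first block = ceil(0.25 · p) attributes |
| `shrink_factor` | 0.25 | next block size = ceil(0.25 · current), floor 1 |
| `max_consecutive_failures` | 5 | failures before rescue check and shrink |
| `tolerance_samples` | 1 | accuracy drop (in samples) a relaxed acceptance may cost |
| `reference` | `previous` | compare trials against the last accepted model (`best`: against the best count so far) |

Trials are judged on correct-classification *counts*, never rounded
percentages, which avoids float-equality hazards. The tested-set and the
failure counter reset on every acceptance and every shrink (the schedule's
"all attributes tested" is read per block-size granularity). When five
consecutive trials have failed, the best rescuable failure in that window
(highest trial count, earliest on ties) is accepted as `ACCEPT_RELAXED` if
one exists; otherwise the block shrinks — or, at block size 1, the run
terminates. Partial blocks are allowed when fewer untested attributes
remain than the block size, and a block never contains all surviving
attributes, so the dataset cannot be emptied; a 1-attribute dataset
terminates immediately with no removals.

With the default `previous` reference, relaxed acceptances can compound:
the invariant maintained is final correct count ≥ initial correct count −
`tolerance_samples` × (number of relaxed acceptances), assertable from the
trial log of every run. Trials are evaluated by LOOCV over the full
dataset; the selection bias this introduces (the held-out sample
influenced which attributes survived earlier trials) is inherent to the
protocol and deliberately not corrected — reported TPR/TNR characterise
the search, not an independent validation.

The engine is fully deterministic: the seed is recorded and threaded to
the learner configuration, but no step draws random numbers. The per-trial
audit log (iteration, block size, block members, reference and trial
counts, decision, failure counter, surviving count) is sufficient to
replay the run: applying the accepted blocks to the initial dataset in log
order reproduces the final attribute set exactly.

## Metrics

TPR = trace of the LOOCV confusion matrix over n (micro average — the
overall accuracy; ×100 gives percentage classification accuracy). TNR =
unweighted macro mean over classes of the one-vs-rest specificity
`TN_c/(TN_c + FP_c)`. Macro averaging was chosen because micro-averaged
specificity collapses to accuracy for two classes, which would make the
two reported columns redundant. A class with zero negatives (or zero
positives) contributes 1.0 by convention and is flagged in the per-class
table.

## Synthetic data

The generator emulates the *shape* of small omics studies: tens of
samples, 30–50 000 attributes, 2–5 classes. Noise attributes are i.i.d.
standard normal regardless of class. Each informative attribute adds a
seed-chosen permutation of class ranks × `effect_size` to the class
members, so adjacent class means differ by `effect_size` within-class SDs.
Options: `sparsity` zeroes a seed-chosen fraction of entries (the
presence/absence character of label-free protein quantitation);
`distribution="lognormal"` exponentiates the Gaussian field for abundance-
like skew; `pairwise_interaction` plants XOR-style paired effects with no
marginal signal, exercising multi-condition rules. Attribute names encode
nothing about informativeness; the ground-truth set is returned separately.

What it does **not** model: probe-level correlation structure, batch
effects, class-dependent variance, peptide-level measurement noise, or
correlated attribute clusters. Consequently, passing tests show the
heuristic's search mechanics and accuracy-preservation guarantees, not its
behaviour on real measurement noise.

## Problem sizes used in the checks

The shipped checks run the full heuristic on tables up to 40 × 200 (five
seeds) and 23 × 178 × 4 classes, with twenty additional smaller runs
(14–24 samples, 30–70 attributes) for the accuracy-floor property; these
sizes exercise every code path — multi-stage block shrinkage, rescue,
partial blocks — while keeping a full run in the low seconds.

## Known limitations

- **Redundant informative attributes are eliminated.** The acceptance rule
  keeps any removal that does not reduce accuracy. When several planted
  attributes carry interchangeable signal (e.g. four parallel 2.5σ
  effects in a 2-class problem), a single one supports the same LOOCV
  accuracy as all four — measured directly: best-single-attribute LOOCV
  equals or exceeds all-four LOOCV on such tables — so the heuristic
  prunes the panel to one representative. This is minimality by design:
  the final panel is *a* sufficient panel, not the complete set of
  class-associated attributes, and recovery-style checks that expect most
  planted attributes to survive will under-count on redundant designs.
- The decision-list learner aggregates evidence weakly compared with
  margin-based classifiers; on data whose classes are only separable by
  combining many weak attributes, the reference accuracy is modest and the
  elimination correspondingly less selective.
- LOOCV inside the search loop means reported accuracies are optimistic;
  for publication-grade estimates, wrap the entire heuristic in an outer
  validation split.
- ARFF support covers the WEKA dialect with numeric features and one
  nominal class attribute; sparse ARFF and string attributes are not
  supported.
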