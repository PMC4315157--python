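# rgife

Rule-guided iterative feature elimination for minimal biomarker panels.

Omics experiments — transcriptomics, proteomics, metabolomics — produce
tables with tens of thousands of measured attributes (genes, proteins) for
a few dozen samples. When the goal is a *clinically usable* biomarker
panel, the question is not which of the 50 000 attributes correlate with
disease but which **handful** suffice to classify samples accurately. This
package implements a wrapper feature-selection heuristic that answers that
question with a rule-based classifier in the loop: attributes are removed
in ranked blocks, and a removal is kept only when the cross-validated
classification accuracy survives it.

## The heuristic

Plain backward elimination (drop one attribute, retrain, keep the drop if
accuracy holds) is `O(p)` retrainings per removal — hopeless at omics
scale. Three changes make it tractable:

1. **Rule-guided ranking.** The base learner is an ordered decision list of
   threshold rules (`IF geneX > t AND geneY < u THEN class`, first match
   fires, default class otherwise). Each attribute is scored by the number
   of rules across all leave-one-out fold models that test it; elimination
   candidates are drawn from the **bottom** of this ranking.
2. **Block elimination.** Removal is attempted in blocks, initially
   `ceil(0.25 p)` attributes, shrinking to `ceil(0.25 b)` whenever all
   attributes have been tested at the current size or five consecutive
   trials have failed.
3. **Relaxed acceptance.** After five consecutive failures, a failed trial
   whose accuracy drop was worth at most one sample may be accepted anyway
   before the block shrinks.

A *trial* removes a block and re-runs leave-one-out cross-validation
(LOOCV, n folds for n samples). Let `c_ref` and `c_trial` be the
correct-classification counts with and without the block; the trial is
accepted when `c_trial >= c_ref`. On acceptance the block is gone for
good, the reference moves to the new model, and the ranking is recomputed
from the accepted fold models. The run terminates when blocks are single
attributes and either every survivor has been tested or five consecutive
trials each lost more than the tolerance.

Reported metrics follow the field's convention: TPR (sensitivity) is the
proportion of correctly classified samples — ×100 it is the percentage
classification accuracy — and TNR (specificity) is the unweighted mean
over classes of the one-vs-rest proportion of negatives correctly
classified.

## Worked example

Generate a synthetic 20-sample × 50-attribute table with 3 planted
informative attributes, then run the heuristic:

```sh
$ rgife synth --seed 11 --samples 20 --attrs 50 --informative 3 --classes 2 --out s.csv
wrote s.csv (20x50) and s.truth.tsv

$ rgife run --data s.csv --class-col class --seed 11 --out out/
attributes: 50 -> 1
correct (LOOCV): 16 -> 17 of 20
TPR: 0.8500  TNR: 0.8500
outputs: 6 files in out/
```

The run reduced 50 attributes to a 1-attribute panel while *improving*
LOOCV accuracy from 16/20 to 17/20 — pruning noise attributes removes
spurious rule conditions. The surviving attribute is one of the three
planted informative ones (`s.truth.tsv` lists them). The final decision
list (`out/ruleset.txt`):

```
IF attr0014 > 1.325975088 THEN class0
IF attr0014 < 0.5552609153 THEN class1
IF attr0014 > 0.8510789049 THEN class1
DEFAULT class0
```

`out/` also contains the reduced dataset (`reduced_dataset.csv`), the
final attribute ranking (`ranking.tsv`), the per-trial audit log
(`trace.tsv`: every block tried, the reference and trial correct counts,
and the ACCEPT/ACCEPT_RELAXED/REJECT decision) and a `summary.json` with
counts, metrics and the full configuration. Identical input, seed and
configuration reproduce all of them byte for byte.

The same pipeline is available as a library:

```python
from rgife import RGIFEConfig, load_csv, run_rgife

dataset = load_csv("s.csv", class_column="class")
result = run_rgife(dataset, RGIFEConfig(seed=11))
print(result.final_dataset.attribute_names, result.final_evaluation.tpr)
```

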