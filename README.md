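# disnet — network-based disease-gene prioritization

`disnet` predicts whether a protein is disease-related from its position in
a protein–protein interaction (PPI) network, and then mines the
classifier's *confident mistakes* for novel disease-gene candidates.  It is
aimed at computational biologists who have an interactome (a two-column
edge list of gene symbols) and a disease–gene annotation table (gene,
disease ID, disease name, supporting PMIDs) and want an interpretable,
reproducible prioritization pipeline.

## The method

Ten per-protein features are computed on the network: degree, closeness,
betweenness, stress, eccentricity, radiality, neighborhood connectivity,
topological coefficient, clustering coefficient, and the **disease neighbor
ratio**

```
DNR_i = n_disease(i) / k_i
```

— the fraction of protein *i*'s direct interaction partners that carry a
disease annotation (k_i is the degree).  Proteins with ≥ k_min disease
annotations are positives, unannotated proteins negatives, and weakly
annotated proteins (0 < count < k_min) are excluded from training.

An **alternating decision tree** (ADTree) is trained by confidence-rated
boosting: the root prediction value is ½·ln(W₊/W₋), and each boosting round
adds the decision rule (precondition, attribute ≥ threshold) minimizing

```
Z = 2(√(W₊(c∧r)W₋(c∧r)) + √(W₊(c∧¬r)W₋(c∧¬r))) + W(¬c)
```

with smoothed branch values a = ½·ln((W₊+ε)/(W₋+ε)).  An instance's
confidence score is the *sum* of all prediction values along every branch
it satisfies; score > 0 means positive.  Bootstrap resampling yields an
ensemble whose rule conservation annotates the reference tree
(red ≥ 90 %, orange ≥ 70 %, …), evaluation is by stratified 10-fold
cross-validated ROC/AUC (FPR = FP/(FP+TN) vs TPR = TP/(TP+FN)), and
negative-class proteins scoring above a confidence cutoff are reported as
candidate disease genes together with the disease profiles of their first-
and second-order network neighbors.

A synthetic-data module generates preferential-attachment networks with
random-walk disease modules matching the annotation statistics of real
interactome releases (32 % of proteins annotated, 4.3 diseases per
annotated protein), so the entire chain is testable without any download.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from disnet import generate_scenario, build_dataset, train_adtree, score_frame
from disnet.evaluation import cross_validate, roc_curve, sensitivity_at_zero
from disnet.candidate_miner import rank_false_positives
import pandas as pd

scenario = generate_scenario("paperlike", seed=1)
dataset = build_dataset(scenario.net, scenario.annotation, k_min=1)
print("dataset:", dataset.counts())

cv = cross_validate(dataset, folds=10, seed=1)
print(f"cross-validated AUC: {roc_curve(cv['score'], cv['label']).auc:.3f}")
print(f"sensitivity at score > 0: {sensitivity_at_zero(cv['score'], cv['label']):.3f}")

model = train_adtree(dataset, n_iterations=20)
X, _ = dataset.training_frame()
scores = pd.Series(score_frame(model, X), index=X.index)
candidates = rank_false_positives(scores, dataset.labels.loc[X.index], min_confidence=0.5)
print(f"{len(candidates)} unannotated proteins score >= 0.5")
print(candidates.head(3).to_string(index=False))
```

prints

```
dataset: {'k_min': 1, 'n_pos': 640, 'n_neg': 1360, 'n_excluded': 0, 'n_total': 2000}
cross-validated AUC: 0.730
sensitivity at score > 0: 0.364
9 unannotated proteins score >= 0.5
protein  confidence  rank
 G00030    1.375579     1
 G00045    1.375579     2
 G00025    0.717394     3
```

Of 2000 synthetic proteins, 640 (32 %) carry a disease annotation; the
classifier separates annotated from unannotated proteins with AUC 0.73
under 10-fold cross-validation, and nine unannotated proteins score above
the 0.5 confidence cutoff — these are the candidates whose network
neighborhoods the dossier stage then profiles (`G00030`'s score of 1.38
means it reached strongly positive prediction branches despite having no
annotation of its own).

The same pipeline runs from the shell:

```bash
disnet run --scenario paperlike --seed 1 --out runs/demo     # end-to-end
disnet simulate --scenario hidden_genes --seed 3 --out sim/  # emit TSVs
disnet features --edges sim/edges.tsv --annotations sim/annotations.tsv --out features.csv
```

`disnet run` writes the feature table, dataset summary, model JSON,
conservation-annotated consensus tree (JSON + Graphviz DOT), ROC table with
AUC, ablation table, candidate report and Markdown dossier into the run
directory, all stamped with the configuration hash and seed.

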