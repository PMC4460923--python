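# Methods

## Problem and model

`disnet` asks whether a protein's position in the protein–protein
interaction (PPI) network predicts a relationship to human disease.  Each
protein `i` in an undirected simple interaction graph is described by ten
features: degree, closeness, betweenness, stress, eccentricity, radiality,
neighborhood connectivity, topological coefficient, clustering coefficient,
and the **disease neighbor ratio**

    DNR_i = n_disease(i) / k_i,

the fraction of `i`'s direct interaction partners annotated to at least one
disease (`k_i` is the degree; DNR of an isolated node is defined as 0, since
the ratio is 0/0 there).  Proteins annotated to at least `k_min` distinct
diseases form the positive class; proteins with no annotation at all are
negative; proteins with `0 < count < k_min` are *excluded* from training
rather than relabeled, so raising the threshold prunes weak positives
without contaminating the negative class.

The classifier is an **alternating decision tree** (ADTree) trained by
confidence-rated boosting.  The root prediction value is `½ ln(W+/W-)` (the
class bias).  Each of the `n_iterations` (default 20) boosting rounds scores
every candidate rule — a precondition `c` (a chain of earlier decisions), an
attribute, and a threshold `t` at a midpoint between consecutive distinct
attribute values within `c` — with

    Z = 2 ( sqrt(W+(c∧r) W-(c∧r)) + sqrt(W+(c∧¬r) W-(c∧¬r)) ) + W(¬c),

where `r` is the test `attribute ≥ t`, and adds the minimizer with branch
prediction values `a = ½ ln((W+ + ε)/(W- + ε))`; weights update as
`w ← w·exp(−y·a)`.  An instance's confidence score is the sum of the root
value and every branch value it reaches; the sign gives the class
(`score > 0` ⇒ positive), the magnitude the confidence.  A test value equal
to the threshold follows the left (`≥`) branch.

## Numerical and design choices

* **ε = 1** (Laplace-style smoothing of branch values).  Because the
  smoothed value lies between 0 and the unsmoothed minimizer of the convex
  per-region loss, total instance weight is non-increasing every iteration;
  this is asserted during training-related tests.
* **Tie-breaks** among equal-Z rules: attribute name lexicographically, then
  precondition creation order, then smallest threshold — builds are fully
  deterministic, so a seed is unnecessary for training itself.
* **Shortest-path metrics** are computed by a level-synchronous matrix
  formulation of Brandes' algorithm (distance matrix from
  `scipy.sparse.csgraph`, then path counts and two backward dependency
  accumulations as masked sparse–dense products).  Betweenness is
  unnormalized with each unordered source–target pair counted once; stress
  counts shortest paths through a node; radiality and the topological
  coefficient follow the Cytoscape NetworkAnalyzer definitions, each
  isolated in one function so a variant can be swapped.  Isolated nodes get
  0 for every distance-based quantity.  The learned thresholds are
  data-driven, so the absolute scale of these metrics does not affect
  classification, only the printed threshold values.
* **Feature selection** (preliminary, reported but not used to restrict the
  classifier) is greedy forward search under a correlation-based subset
  merit: symmetric uncertainty between 10-bin equal-frequency discretized
  features and the class, penalized by mean feature–feature redundancy.
  Binning operates on raw values so heavily tied features (DNR's zeros)
  stay in one bin and the result is row-order independent.
* **Evaluation**: stratified 10-fold cross-validation; each instance is
  scored once by a model that never saw it.  ROC curves sweep the distinct
  scores descending with tied scores grouped; AUC is the trapezoid
  integral, which equals the tie-corrected Mann–Whitney statistic (verified
  to 1e-12 in tests).  Sensitivity for ablation deltas is the TPR of the
  hard rule `score > 0`.  By default the DNR column is computed once from
  the full annotation, mirroring how a practitioner computes features before
  splitting; a strict mode recomputes DNR per training fold for
  leakage-free estimates.
* **Bootstrap consensus**: B (default 100) trees trained on size-n
  resamples; a reference rule counts as conserved in a resampled tree when
  attribute and precondition path match and the threshold agrees within
  0.25 of the attribute's interquartile range (bootstrap thresholds jitter
  while rule structure is stable).  Conservation fractions are binned at
  0.9/0.7/0.5/0.3/0.1 for rendering.  The reference tree is the full-data
  tree.
* **Candidate mining** uses the full-data model's resubstitution scores by
  default (an out-of-fold mode is available): negative-class proteins with
  confidence ≥ 0.5 are ranked, and each candidate's first-order (direct)
  and second-order (distance exactly 2, excluding the protein and its
  direct neighbors to avoid double counting) neighborhoods are profiled by
  per-protein disease counts.

## The synthetic study conditions

Real interactome/annotation releases are registration-gated, so the whole
chain is exercised on synthetic data whose generator reproduces the
statistical structure the method exploits:

* a preferential-attachment network (heavy-tailed degrees, connected);
* disease modules grown by random walks from degree-biased seeds, so
  annotations cluster in network neighborhoods;
* an annotated fraction of 0.32 and a mean of 4.3 diseases per annotated
  gene, enforced within ±0.02 / ±0.3 by a generator self-check;
* a configurable annotation-noise fraction placed on uniformly chosen genes.

Default parameters (the `paperlike` preset): n = 2000 nodes, 4 attachment
edges per node, 40 diseases, walk length 12, degree bias 0.25, 10% noise.
The degree bias is deliberately mild: module walks are simple random walks
whose stationary distribution already favors hubs, giving annotated genes
roughly twice the mean degree of unannotated ones; a stronger explicit bias
would make degree a confound that masks the neighborhood signal, whereas
with the defaults the mean DNR contrast between classes exceeds 0.1 and DNR
is the dominant predictive feature — the regime the method is designed for.
Under these conditions the 10-fold cross-validated AUC is ≈ 0.73–0.78 and
removing DNR costs ≈ 5–20 points of sensitivity while removing degree or
neighborhood connectivity costs ≈ 0–3, reproducing the qualitative feature-
importance ordering expected of neighborhood-driven disease data.

Other presets: `null` (n = 1000, all annotation placed uniformly at random
— no feature–label association, CV AUC ≈ 0.5), `strong_signal` (n = 800,
annotated fraction 0.10 concentrated on hubs with degree bias 5 and no
noise — nearly separable, CV AUC ≈ 0.96–0.98), and `hidden_genes`
(paperlike plus five module-embedded genes whose annotations are withheld
and recorded only in a ground-truth sidecar).  Hidden genes are chosen
among non-adjacent genes with at least three neighbors sharing their
module's disease and high connectivity, i.e. genes that *look like* disease
genes in every respect except the missing annotation; the mining stage
recovers a median of 5/5 of them in the top decile of negative-class
scores.

What the synthetic conditions do **not** emulate: literature/study bias
(hub proteins being better annotated because they are better studied),
isoform and identifier-mapping noise, confidence-weighted or directed
interactions, and the true size of human interactomes.  Passing tests
therefore demonstrate correctness of the machinery and sensible behavior on
data with the assumed structure, not performance on any real interactome.

## Problem sizes

Tests and the acceptance script run the paperlike/hidden scenarios at
n = 2000 over 10 seeds, the null at n = 1000 over 10 seeds and the
strong-signal scenario at n = 800 over 5 seeds; the bootstrap consensus in
the acceptance script uses B = 50.  These sizes give stable seed-averaged
estimates while keeping a full run in the minutes range on one CPU.

## Known limitations

* The exact ε and candidate-threshold scheme of the original ADTree
  implementations vary between toolkits; printed rule thresholds are
  therefore implementation-specific even though classification behavior is
  robust.
* With the default (paper-faithful) DNR mode, a protein's feature uses the
  annotation status of its neighbors, including held-out ones; use
  `strict_dnr` for a conservative estimate.
* The greedy feature selection reports an ordering only; the classifier
  always trains on all ten features, matching the reference protocol.
* Bootstrap conservation matches rules structurally; semantically
  equivalent trees with reordered interchangeable rules count as
  mismatches.
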