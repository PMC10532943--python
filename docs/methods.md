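# Methods

This note documents the models, conventions, and design choices behind
`scmarkers`. The package finds marker genes in a labeled cells × genes
expression matrix by (1) ranking genes with five schemes, (2) scanning
growing prefixes of each ranked list with cross-validated classifiers
(incremental feature selection, IFS), and (3) decompiling decision trees
trained on the selected genes into threshold rules.

## The data model

All stages consume a `LabeledDataset`: a dense cells × genes matrix of
finite nonnegative reals with unique gene/cell ids and a class label per
cell. Expression values are treated as arbitrary nonnegative quantities
(typically `log1p` counts); no stage depends on the normalization, so any
monotone per-gene transform upstream is acceptable.

## Synthetic data generator

The generator emulates a cell-type-annotated scRNA-seq matrix:

* **Counts** are negative binomial via the gamma–Poisson mixture
  `lam ~ Gamma(theta, mu/theta)`, `count ~ Poisson(lam)`, with baseline
  mean `mu = 2.0` and dispersion `theta = 2.0` per gene. These describe a
  moderately expressed, overdispersed gene of the kind that survives
  routine expression filtering (variance `mu + mu²/theta = 4` at the
  default).
* **Markers**: each class owns `markers_per_class` disjoint genes whose
  mean is multiplied by `exp(effect_size)` in cells of that class
  (default effect 2.0, i.e. ≈7.4-fold elevation).
* **Dropout** zeroes each entry independently with probability 0.1 —
  a mild, technology-agnostic stand-in for zero inflation.
* **Imbalance**: the `"colon-immune:<total>"` profile rescales the
  published 25-subtype cell counts of the Gut Cell Atlas normal-colon
  immune compartment (41,650 cells; largest/smallest = 1252×) to the
  requested total by largest-remainder rounding with a floor of 2 cells
  per class (2 is the minimum SMOTE can handle).
* Values are stored as `log1p(count)`; output is a pure function of the
  spec including its seed.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, gene–gene correlation beyond the class structure, library-size
variation, or the real data's per-gene mean/variance spectrum. Passing
tests on this generator therefore demonstrate the pipeline's correctness
and its statistical behavior under idealized class-conditional shifts, not
performance on any particular real dataset.

The standard benchmark instance used by the tests and the acceptance
script is 25 classes × 2,000 genes × 5 markers/class, effect 2.0,
`colon-immune:3000`. At this scale the profile's floor produces six
classes with only 2–3 cells; see *Known limitations*.

## Feature ranking

All rankers return the full gene set ordered by score descending with a
deterministic tie-break (gene id ascending). Fixed dataset + seed gives
identical lists.

* **lasso** — one binary L1-penalized logistic fit per class
  (one-vs-rest, liblinear); score = max |coefficient| across classes, so
  genes driven to zero in every fit rank last. Two deliberate choices:
  the inverse penalty is `C0 / n_cells` (default `C0 = 1000`), which makes
  the fitted optimum — hence the ranking — exactly invariant to
  replicating the dataset's rows; and classes are inverse-frequency
  weighted so that markers of minority classes are not penalized away
  merely for supporting few cells.
* **gbt** — a LightGBM multiclass ensemble at library defaults
  (100 boosting rounds, one tree per class per round); score = number of
  splits on the gene across the ensemble, a nonnegative integer, so the
  scores sum to the ensemble's total split count.
* **mcfs** — s = 100 random gene subsets of size m = ceil(0.1 · p),
  t = 5 trees per subset, each tree trained on a random 2/3 sample split
  with the entropy criterion. Relative importance of gene g:

      RI(g) = Σ_trees (wAcc)^u · Σ_{nodes on g} IG(node) · (n_node/n_train)^v

  with u = v = 1, `wAcc` the tree's mean per-class recall on its held-out
  third, and IG the node's information gain. Genes never sampled score 0.
  These are the published defaults of the Monte Carlo feature-selection
  method; they are configurable.
* **mrmr** — expression discretized per gene into 3 states at
  mean ± 1·std (the canonical discretization; equal-frequency binning
  available), then greedy selection: first the gene maximizing I(g; class),
  thereafter argmax of I(g; class) − mean_{s∈selected} I(g; s) (the MID
  "difference" criterion; the MIQ quotient is available). The list order
  is the selection order and scores are the round criterion values;
  unselected genes follow with absent (NaN) scores. By default 500 genes
  are selected — enough to populate any reasonable IFS cap while keeping
  the quadratic redundancy term tractable; with more than `max_prefilter`
  (5,000) genes, candidates are pre-filtered by relevance.
* **rf** — scikit-learn random forest (100 trees) mean-impurity-decrease
  importance by default; permutation importance (held-out accuracy drop
  when one gene's values are shuffled, 2/3 stratified split, 5 repeats)
  via `importance="permutation"`. The impurity default matches the common
  library default; the permutation variant matches the
  performance-before/after-removal description of the importance concept.

## Class balancing (SMOTE)

Synthetic minority samples are `x + λ(x_nn − x)` with `x` a real minority
sample, `x_nn` one of its k = 5 nearest same-class neighbors (Euclidean),
λ ~ U[0, 1). Every class is grown to the largest class's count; original
rows are preserved verbatim.

Placement: by default SMOTE runs **inside** each CV fold, on the training
part only, and in the currently evaluated gene subspace (the classifier
only sees that subspace, so neighbors are found where the interpolation
happens). Balancing the whole dataset before splitting leaks interpolated
near-copies of test cells into the training side and inflates every
metric; that variant is kept behind `before_cv=True` for comparability
and is demonstrated (not recommended) in the tests. Inside CV, a training
fold can contain a single cell of a 2-cell class; such singletons are
grown by duplication, since interpolation needs two points. The
standalone `smote()` API instead raises on singleton classes, with
instructions, because silently duplicating would misrepresent the
contract.

## Metrics

Per-class precision/recall/F1 from the pooled out-of-fold confusion
matrix, with the 0/0 → 0 convention. Macro F1 is the unweighted mean;
weighted F1 uses weights `w_i` = proportion of class i among the **true**
labels of the evaluated samples (which, under default SMOTE placement,
are real cells only). Accuracy is trace/n. The multiclass Matthews
correlation coefficient is the Pearson correlation between one-hot truth
and prediction matrices — the covariance normalization constant cancels
in the ratio, so unnormalized centered sums are used — with the 0/0 case
(constant truth or prediction) defined as 0. For two classes it equals
the classical binary MCC, which the tests verify against a closed form
and an independent library oracle.

## Incremental feature selection

Prefix subsets of sizes s, 2s, … (default interval 10) up to a cap
(default 2,000) are each evaluated by stratified 10-fold CV. The folds
are built by dealing each class's shuffled members round-robin, so
classes smaller than the fold count are tolerated (they are simply
absent from some folds, logged); folds are fixed per run and shared by
every subset size, so records are prefix-independent — the record at
k = 50 is identical whether the cap is 200 or 2,000.

The **optimal** size maximizes weighted F1 (ties → smallest k). The
**feasible** size is the smallest k whose weighted F1 is within
`feasible_delta` (default 0.04) of the maximum — a reproducible reading
of "almost as good with far fewer genes"; the default covers the
0.011–0.035 gaps between optimal and small-subset classifiers typically
observed with random forests on data of this kind.

Classifier hyperparameters default to the scikit-learn defaults
(unbounded decision tree; 100-tree forest), seeded per fold from the run
seed.

## Rules

One decision tree per feature list is trained on **all** cells (no
oversampling by default — the rules should describe real cells; a flag
enables balancing first) restricted to the list's DT-optimal gene count.
Each leaf becomes one rule: the conjunction of `gene <= t` / `gene > t`
predicates along the root-to-leaf path, predicting the leaf's majority
class, with the leaf's support and purity attached. Repeated predicates
on one gene along a path are kept as-is, preserving the literal path.
The rules of a tree partition the feature space, so `apply_rules` must
match exactly one rule per sample — the equivalence with the source
tree's predictions is the module's central oracle and is also re-checked
inside the pipeline on the training data itself. Thresholds are stored
at full precision in JSON and 4 significant digits in text output.

Cell types are clustered on the binary class × gene incidence of
rule-associated genes using Jaccard distance and average linkage; rows
are pre-sorted by class name so ties merge deterministically.

## Reporting

The Venn decomposition of the five top-k sets enumerates all 31 method
combinations with the genes exclusive to each; region counts sum to the
union size. Following the analysis flow, rule trees use the DT-optimal
sizes and the Venn table uses the RF-feasible sizes (both overridable).
The pipeline writes feature lists, IFS curves for both classifiers, a
15-row optimal/feasible summary, rule groups with per-class counts and
dendrograms, the Venn table, and a parameter manifest; all outputs are
deterministic functions of config + seed (byte-identical on re-run). GO
and KEGG enrichment of selected genes is out of scope: the gene lists
are exported for external enrichment tools instead.

## Problem sizes

The bundled benchmark runs at desk scale: 3,000 cells × 2,000 genes.
IFS scans on this benchmark are evaluated at subset sizes 100 and 200
with the full 10-fold CV (each fold's SMOTE-balanced training set holds
~22,500 samples, which dominates the cost); the tests' unit-level
instances are a few hundred cells. These sizes were chosen so a complete run (five rankings + an IFS
scan) finishes in minutes on one CPU while still exhibiting the severe
imbalance and high class count the method targets.

## Known limitations

* At 3,000 cells, the 1252-fold "colon-immune" profile gives six classes
  only 2–3 cells. Markers of those classes are supported by ~2
  observations among 3,000; the mutual-information signal of such a gene
  (~2·10⁻³ nats) is below the finite-sample MI bias floor
  ((R−1)(L−1)/2n ≈ 8·10⁻³ nats), impurity-based tree importances are
  diluted by the 2/3000 class proportion, and boosted trees with the
  default 20-sample leaf minimum cannot isolate the cells at all. All
  five rankers therefore miss most markers of those six classes (~30 of
  125 planted markers), an information floor of the scaled-down study
  conditions rather than an implementation property; the weighted-F1
  yardstick of the IFS stage is insensitive to it because those classes
  carry ≤ 0.1% of the evaluation weight each. Recovering tiny-class
  markers requires more cells (at the full 41,650-cell scale the
  smallest class has 10 cells) or a detector specifically designed for
  few-cell classes.
* SMOTE interpolates in the selected gene subspace; with very few
  neighbors (k capped at class size − 1) the synthetic points degenerate
  toward segment endpoints.
* mRMR's greedy selection is order-deterministic but not globally
  optimal; its cost is O(n_select · p) MI evaluations.
* The IFS grid evaluates prefixes only; it never searches non-contiguous
  gene subsets.
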