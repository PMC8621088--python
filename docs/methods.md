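# Methods

## Problem and model

`haini` predicts the *type* of a directional drug–drug interaction. A
record is an ordered pair (victim A, perpetrator B) with a class label in
1..19 drawn from a catalog of sentence templates ("the serum concentration
of DRUG_A can be increased when combined with DRUG_B", ...). The model is a
standard multiclass classifier over a hybrid feature row built from two
independent sources: pairwise combinations of per-drug molecular
descriptors, and a signed CYP450 interaction vector. The working assumption
is that interaction type is largely determined by (a) which metabolising
enzymes the two drugs share in victim/perpetrator roles and (b) coarse
physicochemical properties of the two structures.

## Descriptor panel

The descriptor set is a fixed, ordered panel of 60 RDKit descriptors:
20 constitutional counts (molecular weight, H-bond donors/acceptors, ring
counts, ...), 20 topological/shape indices (Chi connectivity, Kappa shape,
Balaban J, Bertz complexity, Labute ASA, TPSA) and 20 physicochemical and
surface terms (LogP, molar refractivity, the ten MR-VSA bins — exposed
under the names MRVSA1..MRVSA10 — and eight SlogP-VSA bins). The panel
lives in `chem_features.DEFAULT_DESCRIPTOR_NAMES` behind a provider
interface so alternative descriptor backends can be plugged in; its length
fixes the operator dimensionalities (60² = 3600 cross-product features,
2·60 = 120 for the other two operators). SMILES are canonicalized before
descriptor computation and results are cached on the canonical form, so
respellings of a molecule are guaranteed identical rows. Descriptors that
evaluate to NaN/inf are imputed to 0 with a logged warning: this keeps
matrices dense and deterministic at the cost of conflating "missing" with
"zero" for a handful of degenerate molecules. Descriptors are deliberately
*not* z-scaled before combination — the cross-product operator is
scale-covariant and tree models are scale-free; a user fitting the
logistic-regression head on wide-range features should scale externally.

## Combination operators

`cross_product` lays out all p² products row-major with the victim index
outer (`k = (i−1)p + j`, names `A:<i>*B:<j>`), so swapping the arguments
transposes the matrix — pair order is semantic everywhere in the package.
`sum_product` uses a blocked layout (all sums, then all products), chosen
as the simplest reading of the bracketed definition and fixed here so tests
are unambiguous.

## CYP450 encoding

The enzyme panel order (1A2, 2A6, 2B6, 2C18, 2C19, 2C8, 2C9, 2D6, 2E1,
3A4, 3A5, 3A7) is immutable within a run. Victim vector: 1 where the drug
is a substrate. Perpetrator vector: +1 inhibitor, −1 inducer, 0 otherwise.
A drug may be substrate and perpetrator of the same enzyme (the encodings
are independent), but an inhibitor+inducer conflict on one enzyme is a hard
error by default because silently resolving it would corrupt signs;
`conflict_policy` accepts `prefer-inhibitor`, `prefer-inducer` or `zero`
for curated data known to carry both annotations. The pair feature is the
elementwise product — 12 signed integers appended unchanged to the hybrid
row (no reverse-direction block by default, keeping the row at 94+12=106).

## Feature selection

Two rankings on training rows only: impurity-based random-forest
importance (seeded, 100 trees by default) and per-feature one-way ANOVA F.
Constant features score 0 in both. The consensus rule grows a shared
prefix length m until the intersection of the two top-m lists holds ≥ k
features, then truncates to k by mean rank with lexicographic tie-breaks —
a deterministic formalisation of "important in both rankings". Whether a
fixed k or a score threshold is the better stopping rule is genuinely open;
k = 94 is the default and is fully configurable.

## Oversampling

Class sizes are long-tailed, so the training split is rebalanced after
selection. The default is SMOTE proper: synthetic minority rows are convex
combinations `x + u(x_nn − x)`, u ~ U(0,1), of a row and one of its k = 5
nearest same-class neighbours (k auto-reduced to class size − 1; a
singleton class falls back to duplication with a warning). A
`method="duplicate"` option does plain random oversampling for users who
prefer no synthetic interpolation. Balancing is applied only to training
data — after the 70/30 split, and (inside grid search) the balanced
training set is what the CV folds partition. Note the oversampling
amplifies whatever label noise the minority classes carry; this is the main
reason classes below the cutoff threshold are dropped rather than
oversampled (see below).

## Classifiers and grids

Standard scikit-learn / XGBoost implementations behind a uniform
`ModelSpec`/`grid_search_cv` surface: exhaustive grid search, stratified
5-fold CV (shuffled, seeded), macro-F1 selection, refit on the full
training input. Labels are internally encoded to 0..k−1 and decoded on
prediction; feature alignment is by column name, so column order never
matters. Grid notes: the naive-Bayes grid is over `var_smoothing` (a
C/gamma/kernel grid describes an SVM, which is available as the optional
`svm` algorithm); the XGBoost grid maps feature subsampling to
`colsample_bytree` and unlimited depth to `max_depth=0`; logistic
regression defaults to l2/lbfgs. The full default grids are large — runs
meant to finish quickly should pass an explicit sub-grid, as the bundled
quickstart config does.

## Synthetic data generator

The generator emulates the *shape* of curated interaction data, not its
chemistry. Drugs: SMILES assembled from a fragment grammar (8 two-site
scaffolds × 20 substituents per site, spelled so every combination is
valence-legal) plus independent per-enzyme CYP roles — substrate with
probability 0.35, inhibitor 0.12, inducer 0.08 (mutually exclusive
perpetrator roles, so generated profiles never conflict). These rates give
roughly 42 % CYP-silent pairs, a realistic mix of metabolic and
non-metabolic interactions.

Labels follow a documented decision table (constants in
`synthetic_data.py`): the first nonzero enzyme of the pair's interaction
vector maps inhibition to classes 1–6 and induction to 7–12; CYP-silent
pairs are classified by two descriptor products that are themselves
cross-product features — `u = MolLogP(A)·MolWt(B)` binned at (120, 320)
with a >480 tail class 19, and `w = TPSA(A)·MolMR(B)` split at 1250 —
giving classes 13–18. The thresholds were fixed once from the grammar's
descriptor ranges to spread silent pairs across their classes. Class sizes
are shaped to a geometric profile (decay 0.75 per rank, classes ranked by
natural frequency; target counts multinomial, shortfalls redistributed).
Label noise replaces a label with a uniform draw over all 19 classes with
probability ε = 0.05, making the Bayes-optimal accuracy exactly
1 − ε·18/19 by construction — a ceiling any honest pipeline must respect.

What the generator does *not* emulate: real chemical space (the grammar
spans ~3200 skeletons), correlated CYP roles across enzymes, pharmacologic
plausibility of the label templates, or annotation biases of curated
databases. Passing the end-to-end tests therefore shows the pipeline
recovers a planted signal of the assumed form at realistic sizes and noise
— not that it attains any particular accuracy on licensed data.

## Pipeline, seeds, problem sizes

One global seed fans out to per-stage seeds via
`numpy.random.SeedSequence(seed).spawn`, logged and recorded in
`provenance.json`. The low-count cutoff defaults to `min_class_count=50`:
below that, a class's training rows are comparable in number to the label
noise floor (ε/19 of the training set) and oversampling amplifies the
noise rather than the class. The end-to-end verification uses 250 drugs /
5000 pairs with an XGBoost point from the candidate grid (max_depth 10,
100 trees) — at that size the pipeline reaches macro-F1 ≈ 0.9 against the
0.80 target while the measured accuracy stays under the Bayes ceiling; the
feature-recovery check uses 20 replicates of 150 drugs / 1200 pairs and
finds both rule-bearing chemical features in the consensus set in every
replicate.

## Numerical conventions and limitations

Zero denominators in precision/recall yield 0 with a per-class flag; macro
averages cover only classes present in the test labels; AUC for a class
absent from the test labels is reported as missing rather than imputed.
Ranking ties break lexicographically by feature name. The F1 is the
harmonic mean 2PR/(P+R) throughout. Known limitations: impurity-based
forest importance splits credit among correlated cross-product features
(the ANOVA-F leg of the consensus mitigates this); quantitative potency
(Ki/IC50), transporter-mediated interactions and non-CYP metabolism are
out of scope; and the 19-template catalog ships with generic placeholder
texts until curated descriptions are supplied.
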