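# Methods

`varprior` re-creates, end to end, a retrospective variant-prioritization
study design for rare-disease genome sequencing: given the annotated,
clinically filtered variants of a proband and the proband's HPO phenotype
terms, predict which variants the analyst team would return on the
clinical report, and evaluate the prediction both as a binary classifier
and as a per-case ranking system.  Real cohorts of this kind are
controlled-access, so the package ships a seeded synthetic-cohort
generator that reproduces the cohort's statistical shape; every empirical
claim below is one the test suite or `scripts/acceptance.py` computes at
run time.

## Phenotype-to-gene scores

Let the ontology have `P` non-root terms connected by `is_a` edges.  A
term set `S` (a patient's terms, or a gene's curated annotations) is
closed under ancestry: `closure(S) = S ∪ {ancestors of S}`, excluding the
root.  The root is excluded because every closed set would contain it,
adding a constant, uninformative dimension and making cosine similarity
never zero.

**Cosine score.**  Patient and gene are binary vectors in `{0,1}^P` with
bits on their closures; the score is `u·v / (‖u‖‖v‖)`, which for binary
vectors reduces to `|A∩B| / √(|A|·|B|)` on the closed sets.  A zero
vector scores 0 by convention.  Gene vectors receive the same ancestor
closure as patient vectors (symmetry between the two sides).

**Random walk with restart.**  An undirected graph joins term nodes
(ontology edges, weight 1) and gene nodes (gene-annotation edges, weight
`gene_edge_weight`, default 1.0).  With column-stochastic transition
matrix `W`, restart probability `r` and restart vector `p₀` uniform over
the patient's closed term nodes, iterate `p ← (1−r)·W·p + r·p₀` until the
L1 change is below `tol`.  The stationary solution is
`p = r(I −(1−r)W)⁻¹p₀`; gene scores are the stationary mass on gene
nodes.  Mass conservation (Σp = 1 within 1e−10) is asserted on every
call.  Defaults: `r = 0.1`, `tol = 1e−10`, `max_iter = 1000` — the source
method's parameters are not published, so all are configuration.  A flag
restricts the restart mass to the directly annotated terms instead of the
closure.

Each variant inherits the **best score over its overlapping genes**
(genes absent from a score table contribute 0), one feature per method.

## Clinical filter

Six criteria, all configurable: minimum total read depth (default 8),
minimum alternate read depth (default 4), maximum population allele
frequency (default 0.01; a variant absent from the frequency databases
counts as frequency 0.0), at least one predicted transcript effect, at
least one gene–disease association (variants with no gene links fail
here), and absence from an exact-match blacklist of known sequencing
false positives.  Missing depth fields fail conservatively.  The defaults
are realistic placeholders — deployed clinical filters keep their exact
thresholds in local configuration — and no test depends on them.  The
filter logs a per-criterion rejection tally (first failed criterion per
variant, evaluated in the order above).

## Feature encoding

Three annotation shapes map to numeric columns:

* *single numeric* — copied through; missing values take a fixed default
  chosen **outside** the declared expected range on the less-impactful
  side (a missing conservation score errs toward "not conserved");
  allele frequencies and population counts default to 0.0 instead
  (absent from the database means never observed).  Default exteriority
  is validated when a spec file is loaded.
* *multi-value numeric* (one value per transcript, say) — reduced by min
  or max to the single worst (most deleterious / most conserved) value;
  an empty list takes the default.
* *multi-label categorical* — bin-count encoded: one integer column per
  vocabulary label counting occurrences (several ClinVar submissions can
  carry the same classification), plus an `_other` bucket that guards
  against label-dialect drift.  Labels match case-sensitively after
  whitespace trimming.

The shipped reference spec encodes to exactly 95 columns with names
mirroring a clinical annotation engine's inventory (deleteriousness,
conservation, population counts, curated-database bins, splice and
protein-effect predictors, effect categories) padded with documented
generic slots; real deployments differ, so the spec file is configuration.
The two phenotype scores enter the matrix as ordinary numeric features.

**Univariate selection** scores each column independently against the
binary label — ANOVA F by default, chi-square optionally for count
columns — and keeps the top `k = 20`, ties broken by column order.
Selection sees training rows only; permuting or deleting test rows
provably cannot change it.

## Split, classifiers, tuning

**Chronological split.**  Cases are walked in chronological order of
analysis and greedily assigned to the side currently holding fewer
reported positives (ties alternate).  This balances positive totals
(e.g. a 237-case / 378-positive cohort splits 189/189) while keeping
early/late cases evenly mixed on both sides, so drift in scientific
knowledge over the collection period biases neither set.  The published
study states the goals of its assignment, not the algorithm; this greedy
rule is one consistent realization.

**Families.**  Reported variants are ~1:230 after filtering, so each of
the four families carries an explicit imbalance contract:

| family | contract | realization |
|---|---|---|
| `weighted_forest` | trees weight inputs inversely to class frequency | sklearn `RandomForestClassifier(class_weight="balanced")` |
| `weighted_logistic` | class-frequency-weighted logistic regression | sklearn `LogisticRegression(class_weight="balanced")` behind a standardizer |
| `balanced_forest` | each tree fits a class-balanced under-sampled bootstrap | in-package forest over `DecisionTreeClassifier`s, n_minority draws per class per tree |
| `undersampled_boost_ensemble` | random under-sampling, then an ensemble of AdaBoost learners | in-package ensemble of sklearn `AdaBoostClassifier`s, probabilities averaged |

The last two are implemented in-package against these behavioral
contracts using scikit-learn primitives.

**Tuning.**  Exhaustive grid search over an editable YAML lattice;
stratified 10-fold CV (label-only stratification, seeded fold
assignment) records balanced accuracy (class-frequency-weighted
accuracy) and positive-class F1 at the 0.5 threshold per fold; the
configuration with the best mean F1 wins (the appropriate criterion under
heavy imbalance), ties to the first lattice point.  The shipped default
lattice is trees ∈ {100, 200, 500} × depth ∈ {4, 8, ∞}, logistic
C ∈ {0.01, 0.1, 1, 10}, ensemble size ∈ {10, 50}; desk-scale runs (the
acceptance script and the end-to-end tests) use the reduced
`quick_grids.yaml` lattice of one or two points per family.

## Evaluation

As a classifier: ROC with trapezoidal area and precision–recall with the
step-wise average-precision area (trapezoidal PR interpolation is
optimistically biased).  As a ranking system: per case, variants sort by
descending reported-probability with ties broken by variant key
(deterministic; a pessimistic mode assigns ties their worst rank for
sensitivity analysis).  Reported-variant ranks summarize to median (even
counts: mean of the central pair), mean, and top-1/10/20 percentages,
overall and stratified by ACMG class.  Two single-feature baselines —
the scaled deleteriousness score and the phenotype cosine — rank cases
with the same machinery.  Externally scored files that rank only a
subset of variants are completed conservatively: unscored variants are
placed immediately after the last scored one, in key order.

## Synthetic cohorts

Defaults reproduce the reference study conditions: 237 probands; 200–400
filter-passing variants per case plus ~24 designed filter failures
(one per failure mode); 1–3 reported positives per case
(P(1)=0.55, P(2)=0.30, P(3)=0.15, mean ≈ 1.6 — matching a 378-positive /
237-case cohort); ACMG mix 0.59 VUS / 0.22 likely pathogenic / 0.19
pathogenic.

The ontology is a random rooted DAG (each term attaches to one earlier
term, a second parent with probability 0.2); each gene annotates a
coherent subtree neighborhood (mean 8 terms).  Patient terms are the
causal genes' annotation sets with noise — up to 2 true terms dropped, up
to 3 spurious terms added — emulating the variability of real phenotype
collection.  Positives mean-shift 18 designated annotation columns
(12 numeric, 6 categorical-label tilts) by `signal_strength` (default
1.0 SD) scaled by ACMG class (VUS 1.0, LP 1.3, Path 1.6); together with
the two phenotype scores these form 20 signal columns among the 95,
the remainder pure background.  Every annotation is independently
missing with probability 0.10; ~12% of variants overlap two genes.
All randomness flows from one master seed through named substreams, so
the same seed yields byte-identical cohorts.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage and inheritance structure (no trios,
no LD, no coalescent), feature–feature correlations beyond the shared
class shift (real conservation scores correlate strongly with each
other), literature-derived gene–phenotype edges beyond the curated
annotation set, annotation-engine idiosyncrasies, and any specific
disease biology.  Rank-recovery results on synthetic cohorts demonstrate
that the machinery works when its assumptions hold, not that the
published performance numbers transfer.

## Numerical choices and degenerate inputs

Zero-vector cosine is 0; empty RWR restart sets raise; isolated walk
nodes get self-loops so every transition column sums to exactly 1;
non-convergent walks warn and return the best iterate.  NaN payloads are
encoding errors (no NaN survives assembly, asserted).  Constant columns
get −∞ selection scores (never selected ahead of informative ones).
Zero-count strata report `n=0` with undefined metrics flagged rather
than fabricated.  Seeds derived from the master seed stay below 2³¹.

## Problem sizes used in the checked runs

The acceptance script and end-to-end tests run the default 237-case
cohort (~71k filtered variants) with the reduced tuning lattice; the
reproducibility check uses a 24-case cohort; selection recovery uses
40 000 × 95 matrices over 5 seeds; the imbalance contract uses a
100-positive / 20 000-negative training set.  These sizes are the
package's reference desk-scale conditions.

## Known limitations

The exact 95-annotation inventory, filter thresholds and tuned
hyperparameters of any real deployment are site-specific configuration;
the shipped files are faithful-shape stand-ins.  Probabilities are not
calibrated, and the classifier outputs are ranking aids — not automated
reporting decisions.  Only `is_a` ontology edges are interpreted;
`replaced_by` chains of obsolete terms are not followed; no
information-content weighting of terms is applied.
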