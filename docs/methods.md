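# Methods

## Model

The package treats ADR prediction as link prediction in a multipartite
knowledge graph with four node types (drug, ADR, indication, protein
target) and three edge types, each joining a drug to one property node.
The modelling assumption is mechanistic: drugs causing the same ADR share
identifiable properties — targets, indications, co-occurring ADRs — and a
drug resembling the "enriched profile" of an ADR's known causes is a
candidate new cause.

For one ADR the pipeline is: (1) one-sided Fisher enrichment of every
candidate property among the known causes versus all other drugs;
(2) Benjamini–Hochberg FDR control and retention at q < α; (3) a feature
matrix of per-type total adjacency with the retained predictors, min–max
scaled per column; (4) a linear score with non-negative, L2-normalised
weights and a hard threshold, both chosen to maximise Youden's
J = sensitivity + specificity − 1; (5) new predictions = non-cause drugs
above the threshold.

Key structural choices:

- **One-sided (greater) test.** Only over-representation is meaningful for
  the scoring scheme; depleted properties are not usable as positive
  evidence, and with w ≥ 0 they could not lower a score anyway.
- **Candidate universe.** By default only properties adjacent to at least
  one known cause are tested: a table with a = 0 cannot be significant
  one-sided. Skipping those properties changes the number of hypotheses m
  entering BH; `test_all_candidates=True` restores the full universe.
- **FDR family.** Correction is applied within each feature type, because
  the three predictor families are selected and used independently (and a
  model needs ≥ 1 survivor of *each* type). `pooled_fdr=True` pools all
  tests for sensitivity analysis. Retention is strict (q < α), α = 0.05.
- **Label-leakage guard.** The modelled ADR node is excluded both as a
  candidate and from any predictor set; its adjacency is the label. Other
  ADR predictors shared between a cause and the modelled ADR are inherent
  to the design and retained.
- **Scaling.** "Scale to [0, 1] per feature type" forces min–max scaling;
  constant columns map to 0 (they carry no information and this keeps them
  from biasing the threshold). The training-time (min, max) per column are
  stored in the model, and unseen drugs are scaled with them and clipped
  to [0, 1].

## Optimiser

The weight/threshold search is exhaustive and deterministic. Weight
directions are the integer lattice {0, 1, …, 1/step}ⁿ minus the origin,
reduced to primitive vectors (removing duplicate directions), kept in
lexicographic generation order, and L2-normalised; the default step 0.05
gives 7,513 directions for three feature types. For each direction the
candidate thresholds are the midpoints of consecutive distinct sorted
scores plus sentinels below the minimum and above the maximum, so every
achievable confusion matrix is visited. Classification is strict
(score > threshold). J is compared on the integer scale TP·N + TN·P − P·N,
eliminating floating-point ties; remaining ties are broken by higher
specificity, then lower lattice index, then the fewest positive
predictions. A gradient or stochastic optimiser would be faster but the
exhaustive search is exactly reproducible and trivially auditable, and at
a few hundred drugs it costs ~0.2 s per model.

Because the threshold is fit to maximise J, training J is optimistically
biased on null data (the permutation test in the suite bounds this
optimism rather than expecting J ≈ 0 exactly at small n).

## Cross-validation and confidence

Edge-deletion CV splits an ADR's cause edges into k = 10 seeded folds;
each fold's edges are deleted while the drugs remain as true negatives,
predictors are re-selected and the model retrained on the modified graph,
and recovery is the fraction of deleted drugs among the new predictions.
Deleted edges are restored between folds. A *successful* fold (the term is
otherwise undefined) is a non-empty fold whose modified graph yields a
complete predictor set and a trainable model; means cover successful folds
only, and empty folds (ADRs with fewer than k causes) are unsuccessful.
The random-model expectation uses each fold's own prediction count over
its non-cause pool, averaged across successful folds; raw confidence is
mean recovery divided by that expectation. Bins over a collection of ADRs:
high if raw confidence exceeds the median of ADRs with ≥ 6 successful
folds, mid if between 1 and the median, low otherwise or with < 6
successful folds.

## Random-model significance

Against an observation table (drug, ADR, observed) the model's new
predictions are restricted to the eligible non-cause pool (M drugs, K of
them observed associated). Each of n_iter = 100,000 random models draws N
drugs uniformly without replacement; the per-iteration validated count is
drawn directly as Hypergeometric(K, M−K, N), which is distributionally
identical to drawing drug identities. p is the plain count/n_iter of
iterations with ≥ V validated — no small-sample (+1) correction, so p = 0
is possible at extreme V — and significance is strict p < 0.05. E = N·K/M.
The closed-form tail P(X ≥ V) serves as the oracle in tests, never as the
implementation of the null.

## Benchmarks

Logistic regression (L2, defaults), a decision tree (min 5 samples per
leaf) and an RBF-kernel SVM (defaults) are fitted on the same scaled
feature matrix via scikit-learn; their "new predictions" are training-set
false positives. They reproduce comparator behaviour and are not part of
the contribution; `edge_deletion_cv(..., method="LR"|"DT"|"SVM")` runs the
same CV protocol over them.

## Synthetic data

The generator emulates the structure the method assumes, not the marginal
statistics of real pharmacology databases. Defaults: 200 drugs, 100 ADRs,
50 targets, 50 indications; every drug–property edge is Bernoulli(0.05)
except that 15 cause drugs hit 3 planted properties per type at
probability 0.6 and always link to the target ADR; non-causes never link
to the target ADR, so the planted cause set is exactly the label. The
sampled graph passes through the complete-drug filter, which drops ~10–15%
of drugs (occasionally including a cause); ground truth records the
survivors. Sizes keep a full enrich–train cycle under half a second while
leaving the planted enrichment far below q = 0.05. One global seed is
split into independent per-stage streams via `numpy.random.SeedSequence`,
so graph, hold-out and observation generation are independently
reproducible.

What the generator does **not** model: the heavy-tailed degree
distributions of real drug–ADR data (real graphs have a median of a few
causes per ADR but nausea-like ADRs touching most drugs), correlated
properties, or any pharmacological meaning in the identifiers. Passing the
synthetic tests therefore demonstrates correctness of the machinery and
recoverability of a clean planted signal, not expected performance on
public drug databases.

The observation-table generator marks every drug eligible and observes
true (cause, target-ADR) pairs with a chosen sensitivity (default in the
examples 0.8) and all other pairs at a noise rate (0.05) — a stand-in for
an EHR-derived association table, which is upstream of this package (the
30-day single-prescription association logic is explicitly out of scope;
the package consumes the finished table).

## Degenerate inputs and numerical notes

All-positive or all-negative labels raise; an ADR without causes raises; a
predictor selection with any empty feature type returns the distinguished
`NoModel` outcome rather than an error, and pipeline runs log and skip such
ADRs. Fisher p-values come from `scipy.stats.hypergeom.sf` (exact to ~1e-15
for the table sizes involved); BH from `statsmodels`; AUC is the
Mann–Whitney statistic with ties credited ½. Graph I/O is a sorted TSV, so
save → load → save is byte-identical.

## Known limitations

- The reference implementation's optimiser grid is undocumented, so
  per-ADR AUCs on real data reproduce only approximately; the lattice step
  is configurable.
- Training J and training AUC are in-sample quantities; generalisation is
  assessed only through edge-deletion CV and the observation-table null.
- The full-scale reference evaluation requires the published public drug
  knowledge graph, which must be supplied by the user
  (`data/supplementary_graph.tsv`); it is not redistributed here.
- Per-ADR models are independent; drug combinations, chemical
  substructures and ontology-expanded features are out of scope.
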