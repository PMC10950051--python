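# Methods

`adpanel` re-implements, as a tested library, a biomarker-panel analysis
used in Alzheimer's disease cohort studies: hierarchical clustering of a
27-marker panel under pervasive missing data, and random-forest embedded
feature selection for amyloid-PET status and cognitive impairment.  The
cohort the analysis was designed for is not publicly deposited, so the
package ships a synthetic-cohort generator with planted structure; every
claim the test suite makes is therefore a claim about recovery of known,
planted truth, plus three deterministic statistics recomputable from the
published demographic table.

## The panel and preprocessing

A cohort is a subjects × 27 matrix with an explicit missingness mask
(missing cells are NaN, but the mask is authoritative; no downstream
computation ever imputes).  The marker registry covers amyloid PET
(Centiloid), tau PET (SUVR), plasma and CSF Aβ42/40 ratios, CSF p-tau and
t-tau normalised to Aβ40, ten tau phosphorylation-occupancy ratios
(pT111/T111 … pT231/T231), CSF and plasma NfL, an MRI cortical-thickness
signature, CSF Ng/SNAP-25/VILIP-1/YKL-40/sTREM2, CDR-SB, MMSE, and a
polygenic risk score.

Preprocessing: the two NfL markers are natural-log transformed (they are
right-skewed; every downstream step is rank- or split-based, so the base of
the logarithm is inconsequential), then every marker is z-scored over its
non-missing entries (sample SD).  Subjects missing strictly more than 50%
of the markers are excluded.  Amyloid positivity is Centiloid ≥ 16.4
(inclusive).  Impaired (CDR > 0), amyloid-negative subjects are rejected at
load time with a warning, mirroring the analysis population definition.
z-scoring is recomputed within each analysis cohort (entire vs subset); the
alternative — score once on everyone — changes nothing downstream of the
rank-based similarity and changes tree structure only through cut-point
labels, but the per-subset choice is the cleaner reading of "all measures
were z-scored" applied to each analysis.

## Clustering

**Similarity.** Marker similarity is the absolute pairwise Spearman
correlation, computed pairwise-complete: a subject is dropped from a pair's
calculation only if it is missing one of the two markers in question.
Midranks handle ties.  Entries resting on fewer than 3 complete pairs are
undefined and abort clustering (no silent imputation).  |ρ| is a
similarity; linkage runs on the standard conversion d = 1 − |ρ|.

**Linkage.** WPGMA: iteratively merge the closest pair, with the update
d(a∪b, c) = (d(a,c) + d(b,c))/2 regardless of cluster size (scipy's
`weighted` method provides the implementation; tiny hand-computed linkages
act as oracles in the tests).  Pairwise-complete distances need not be
metric; height inversions are flagged with a warning rather than hidden.

**Number of clusters.** For each of 1000 permutations (default), a random
20% of subjects is held out, the eigenvalues of the pairwise-complete
Pearson correlation matrix of the retained subjects are computed (clipped
at zero — pairwise-complete correlation matrices can be slightly
non-PSD — with a warning), and the scree curves are averaged.  The elbow of
the mean curve is the maximum second forward difference,
k = argmax_i (λ_i − 2λ_{i+1} + λ_{i+2}), ties toward smaller k.  This rule
is isolated in one function (`elbow_index`) precisely because "the elbow"
admits several operationalisations; the chosen one returns k = 1 for a
single dominant factor and small k for structureless data, which the tests
pin down.  Holdout resamples subjects, not markers: the point of the
permutation average is stability of the spectrum against cohort
composition.

**Outputs.** Cluster assignments at the selected k, a Newick export of the
dendrogram (merge heights as node heights), a merge-table TSV, and the edge
list of marker pairs with similarity strictly above 0.5 (the machine twin
of a circle plot).

## Random forest with curvature tests and surrogate splits

The trees are written in this package (a compiled numba core with a pure
numpy reference engine; both implement identical semantics and the tests
compare them node for node) because the combination the analysis relies
on — curvature-test split selection, surrogate splits, reduced-error
pruning — is not available in scikit-learn.

**Split-variable selection (curvature test).** At each node, every
candidate predictor is binned into quartiles of its non-missing values at
that node (duplicate bin edges collapse), and a Pearson chi-square test of
independence between bin and class is computed over the observed rows;
degrees of freedom count only non-empty bins/classes.  The split variable
is the p-value argmin.  Exact ties are refined by the pairwise interaction
test (joint quartile cells of two predictors × class), then by smallest
index.  Under boosting, weighted class counts are rescaled so each column's
table total equals its observed-row count, keeping the statistic on the
counting scale.  No multiplicity correction is applied — the p-values are
used only for argmin selection.

**Cut point.** The best Gini-gain threshold on the chosen variable,
searched over midpoints between consecutive distinct observed values, with
both children keeping at least `min_leaf` observed rows.

**Surrogates.** Up to 5 other variables, each with the cut (from its
quartile boundaries at the node, direction free) that best reproduces the
primary split on rows where both variables are observed; agreement must
exceed 0.5 and surrogates are stored in decreasing agreement order.
Restricting surrogate cuts to quartile boundaries is a deliberate
computational choice; agreements are typically within a few percent of the
unrestricted optimum and the routing behaviour is what the tests pin.

**Routing.** Observed rows follow the primary split; rows missing the
primary try surrogates in order.  At prediction time a row missing all
routing variables stops and takes the current node's posterior (an
all-missing row gets the class priors).  During training such rows follow
the heavier child so every training row reaches a leaf.

**Ensembles.** `bag` grows each tree on a bootstrap sample and averages
posteriors; `boost` is SAMME-style adaptive reweighting with shrinkage
(`learn_rate`), stopping early on perfect or no-better-than-chance stages,
and maps the additive class scores to a posterior by softmax.  The
aggregation method is itself a searched hyperparameter.

**Pruning.** Reduced-error pruning: bottom-up, a subtree collapses to a
leaf whenever that does not increase misclassifications on a validation
set; surrogates die with their node.  In the selection protocol each
fold's final model is grown on 80% of the fold-training data and pruned on
the held-out 20%, so pruning always sees data the tree was not grown on.

**Importance.** Embedded (split-gain): for each marker, the Gini risk
reduction summed over all primary splits on that marker, averaged over
trees.  Markers never split on score exactly zero.  Split-count and
permutation importances are deliberate non-goals; split-gain is the
standard embedded-selection reading.

## Hyperparameter search

A small Gaussian-process Bayesian optimizer (RBF kernel with fixed
lengthscale 0.3 on the unit-cube encoding, standardized objective,
expected-improvement acquisition over 256 seeded random candidates per
iteration; the first quarter of the budget is a random design).  The search
space: method ∈ {bag, boost}; n_cycles ∈ [10, 500] log-scale; learn_rate ∈
[10⁻³, 1] log-scale (boosting only); min_leaf ∈ [1, n/4] log-scale;
max_splits ∈ [1, n−1] log-scale.  The objective of one evaluation is the
misclassification rate of an inner k-fold CV (default 10-fold), with the
inner split held fixed across evaluations (common random numbers).  The
incumbent after the iteration budget (default 300) is returned.  Fixed GP
hyperparameters keep the optimizer fully deterministic under a seed; on an
analytic test function it localises the minimum within 5% of the range in
30 evaluations and never loses to random search at equal budget (median
over seeds, asserted in the tests).

## The gated feature-weight protocol

For each of 10 outer stratified folds: run Bayesian optimization on the
training portion; fit the incumbent (80/20 grow/prune split); evaluate
sensitivity and specificity on the held-out fold.  Folds whose model
reaches both ≥ 0.8 contribute their importance vector; the contributions
are averaged, then min-max rescaled to [0, 1] (averaging before rescaling),
and markers below 0.5 are flagged weak.  If no fold passes, the protocol
fails loudly ("no qualifying model") — a structureless panel must produce
this error, and the tests check that it does across seeds.  Outcome
circularity guards: amyloid PET is removed from the amyloid model's
predictors; CDR-SB **and** MMSE are removed from both cognition models
(CDR-SB shares the outcome's scale, so dropping only MMSE would leak).

## The synthetic cohort

A Gaussian factor model chosen because every downstream step is rank- or
split-based.  Groups CN(A−)/CN(A+)/CI have sizes 211/228/88 exactly.  Four
planted blocks mirror the field's biological themes: core pathology (13
markers, factor loading 0.45), neurodegeneration (3 markers, 0.92),
AT8-epitope sites (3 markers, 0.89), dysfunction/inflammation (5 markers,
0.88); a marker with loading ℓ equals ℓ·factor + group effects +
√(1−ℓ²)·noise, so the within-block correlation is ℓ² plus the shift
contribution.  Markers that decrease with pathology (the Aβ ratios, the
cortical signature, MMSE) load negatively; the NfL markers are
exponentiated to a positive, skewed raw scale so the preprocessing has
something real to do.

Three markers (MMSE, pT175/T175, PRS) belong to no block.  They are not
fully independent noise: each carries a weak tether (|loading| 0.30–0.45,
below the 0.5 edge threshold) to a neighbouring factor.  With exactly zero
correlation they would be the outermost leaves of every dendrogram and a
k = 4 cut could only ever isolate them as singletons; weak tethering keeps
them outside all blocks at the similarity level while letting the four-way
cut separate the planted blocks — and is also the more realistic choice
(MMSE correlates weakly with CDR-SB, pT175 with the other AT8 sites).

Group effects act along two axes.  The amyloid axis (−0.9, 0.7, 0.9 across
the groups) shifts the core factor at 0.65 strength and, much more
strongly, five designated markers directly (pT217/T217 1.2, pT111/T111 1.1,
p-tau/Aβ40 1.0, Aβ42/40 −0.95, pT231/T231 0.9) — these five are the
planted "strong amyloid predictors" the selection protocol must recover.
The impairment axis elevates the CI group on the neurodegeneration factor
(0.85), CDR-SB (1.3), tau PET (0.5), pT205/T205 (0.45) and lowers MMSE
(−0.6); it is orthogonalised against the amyloid axis under group-size
weighting at generation time so group structure does not induce
between-block correlation.  Block loadings were calibrated once, at design
time, so that (i) the four leading eigenvalues of the marker correlation
matrix descend roughly linearly before the cliff to the noise floor — a
13-marker block with realistic loadings otherwise produces one dominant
eigenvalue and *any* curvature-based elbow rule collapses to k = 1 — and
(ii) a gated model at 0.8/0.8 is attainable (a linear reference classifier
reaches ≈ 0.92/0.92 on the planted five).  The constants above are frozen;
they are the package's study conditions, not tuning knobs.

Missingness is MCAR at 10% per marker (the pairwise-complete estimator is
unbiased under MCAR), plus 4% of subjects forced to 15/27 missing markers
to exercise the exclusion rule.  Demographics (age, education, sex, race,
APOE ε4) are drawn per group from the shipped reference summary table.
Centiloid labels are generated consistently with group membership around
the 16.4 threshold (uniform below; shifted exponential above).

What the generator does **not** emulate: real marker-specific missingness
patterns (which are not MCAR and differ by modality), heavy-tailed or
skewed marker distributions beyond NfL, measurement batch effects, and the
real cohort's exact correlation values — only its qualitative block
topology.  Passing recovery tests therefore show the pipeline recovers
planted structure of realistic shape and strength under MCAR missingness;
they do not certify behaviour under informative missingness (an MNAR
stress-test is a natural extension, and surrogate splits are the component
it would stress).

## Problem sizes and numerical choices

Defaults mirror the full protocol (1000 permutations, 300 BO iterations,
10 inner folds).  `AnalysisConfig.scaled()` is the package's reduced
profile — 100 permutations, 30 BO iterations, 2 inner folds, cycle cap 40,
split cap 24 — used by the examples, the recovery experiments and the
acceptance script; scaling only changes precision, never the code path.
Determinism: every stage draws from its own `SeedSequence`-spawned stream,
so identical config + data + seed gives byte-identical outputs, and
scaling one stage's workload never perturbs another's draws.  Ties break
deterministically everywhere (smallest index / smallest k / smallest
threshold).  Degenerate inputs fail loudly by policy: constant columns at
z-scoring, non-positive values at log transform, undefined similarity
entries at linkage, single-class outcomes at selection.

## Known limitations

* The elbow rule is one defensible operationalisation; alternatives
  (Kneedle, explained-variance thresholds) plug into `elbow_index` but are
  not implemented.
* Boosted ensembles are pruned per tree with stage weights left unchanged,
  a mild approximation (pruning is tuned for, and mostly exercised with,
  bagging).
* The GP optimizer uses fixed kernel hyperparameters; it is built for
  5-dimensional, few-hundred-evaluation budgets, not as a general BO
  library.
* Feature weights from strongly correlated predictors split importance
  mass; the protocol ranks the planted five reliably but their relative
  order within the five varies across seeds, as expected for embedded
  importances.
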