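# Methods

This note records the statistical model behind `miregnet`, the defaults
and numerical choices, what the synthetic generators do and do not
emulate, and the design decisions taken where the method leaves room.

## PU score combination

**Model.** A candidate miRNA:mRNA pair is described by a score vector
x ∈ ℝᵈ, one coordinate per upstream prediction algorithm (missing scores
are imputed as 0: the absence of a prediction is treated as evidence
against the interaction for that algorithm; the imputation value is
configurable).  Validated pairs carry the label s = 1; all other pairs are
unlabeled (s = 0), a mixture of true interactions and non-interactions.
The SCAR assumption states P(s = 1 | x, y = 1) = c, a constant *label
frequency* independent of x.  Then P(s = 1 | x) = c·P(y = 1 | x), so a
classifier for the observable labeled-vs-unlabeled problem identifies the
interaction posterior up to the constant c.

**Procedure.**

1. Fit g(x) ≈ P(s = 1 | x) on labeled-vs-unlabeled data.
2. Estimate ĉ as the mean of g over a held-out 20% of the positives
   (Elkan–Noto e1), clipped to (0, 1].
3. Fit the weighted classifier: labeled pairs are positives with weight 1;
   each unlabeled pair enters both as a positive with weight
   w(x) = ((1−ĉ)/ĉ)·g(x)/(1−g(x)), capped at 50 to avoid blow-up as
   g → 1, and as a negative with weight 1 − min(w(x), 1).  Its positive
   probability is the reliability score.

**Ensemble.** Positives are rare, so both stages are bagged: each of
K = 10 members trains on all positives plus `negatives_per_member`
unlabeled examples drawn with replacement (default: as many as there are
positives, giving balanced members).  A pair's score is the average over
the members whose training sample contained it; a pair sampled by no
member falls back to the all-member mean.  Because each member sees only a
subsample of the unlabeled pool, its sampled unlabeled rows carry the
importance weight n_unlabeled / negatives_per_member.  Without this
correction a balanced member would overstate P(s = 1 | x) by roughly the
undersampling odds, which would bias ĉ upward by the same factor; with it,
members remain calibrated against the full pool and e1 recovers c
directly.

**Base learner.** Any probabilistic binary classifier fits the contract;
the default is L2-regularized logistic regression (C = 1).  A linear model
over algorithm scores is a deliberately simple meta-learner that tolerates
the strong collinearity among upstream predictors.

## Biclique extraction (step 1)

The combined scores form the weighted bipartite adjacency matrix A with
entries in [0, 1]; indices are kept lexicographically sorted so every
computation is deterministic.  An interaction is *reliable* when its score
is strictly greater than β (default 0.5).

Degree statistics are computed per direction on the thresholded graph,
over objects with at least one reliable interaction: the mean opposite
degree (e.g. avg_mirna, miRNAs per gene), and the own-degree minimum both
absolute (abs_min_mrna) and outlier-proof (min_mrna, after discarding the
⌊0.0015·n⌋ smallest counts — the lowest 0.15%, i.e. the left 3σ tail of an
assumed Gaussian degree distribution; at small n the trim count is 0 and
no trimming occurs).

Aggregation intersects the seeded side and unions the other, so aggregates
remain bicliques on the thresholded graph by construction.  Admissibility
requires the intersected side to stay ≥ the outlier-proof minimum and the
unioned side ≤ the average opposite degree (kept as a real; comparison is
≤).  The printed admissibility condition in the source description swaps
∩ and ∪ relative to the aggregation rule; this implementation follows the
aggregation definitions and the stated rationale (keep many mRNAs, about
avg_mirna miRNAs).  Among admissible pairs, the pair maximizing
jaccard(C′_r, C″_r) · q(aggregate) is chosen; q is evaluated on the
aggregate as defined.  Ties break on the lexicographically smallest joined
id, making the procedure invariant to input order; pair objectives are
cached and only pairs involving the newest aggregate are re-scored, which
is what makes desk-scale runs fast while remaining step-for-step identical
to exhaustive re-enumeration (tested against a brute-force oracle).

Bicliques with fewer miRNAs than abs_min_mirna or fewer mRNAs than
abs_min_mrna are pruned; abs_min_mirna is not produced by the
miRNA-to-gene statistics and is defined symmetrically from the opposite
direction.  Objects covered by no kept biclique are reported as
isolated/noise.  The two directions' results are merged with exact
duplicates (same C_r and same C_c) collapsed, joining their ids.

## Hierarchy construction (step 2)

Objects are embedded by their raw score profiles — a miRNA by its row of
A, a gene by its column.  No other coordinate space is shared by both
object kinds, and profiles make "separable biclusters" mean exactly
"distinguishable interaction patterns".

*Overlap detection.*  For each pair of biclusters at a level and each
dimension, a linear SVM (C = 1; the separator is a hyperplane, so the
kernel is linear by construction, though configurable) is trained on the
members exclusive to each side and evaluated on the same members; a
misclassified object plausibly belongs to both biclusters and is added to
the one that did not contain it.  Shared members are excluded from
training; a dimension with no exclusive members on one side is skipped.
Additions are collected over all pairs and applied after the pass (batch
semantics), so the result does not depend on pair ordering, and membership
only ever grows within a pass.

*Merging.*  σ(w) is the scalar RMS distance of a cluster's members to
their centroid, because the candidate condition subtracts 2σ from a scalar
Euclidean centroid distance; the condition dist − 2σ′ − 2σ″ ≤ 0 is
inclusive and needs to hold on only one dimension.  A candidate union is
merged only if its compactness exceeds α (strict); a bicluster in several
passing candidacies takes only its maximum-q merge (ties on the smallest
joined id).  Unmerged biclusters are copied to the next level with a
self-parent link, so every level is a complete clustering and a "best
level" can be chosen downstream by rank statistics.  One overlap pass and
one merge pass per round (the overlap pass is re-run each round); building
stops when a round merges nothing or at max_levels (default 10, ample for
hierarchies that in practice reach 5–8 levels).  The q > α guarantee for a
merged parent refers to the union at merge time and is recorded as such
(`merge_q`); a later overlap pass may grow the parent and change its final
compactness.  Structural invariants — merged-parent quality, child ⊆
parent, compactness bounds — are asserted on every built hierarchy.

## Functional ranking (step 3)

Gene-pair similarity is SimGIC on ancestor-closed GO term sets (closure is
the conventional choice for SimGIC and the default; a flag disables it).
IC uses the natural logarithm by default; the base only rescales numerator
and denominator jointly when term sets coincide, not in general, so it is
exposed as a parameter.  `is_a` and `part_of` are both treated as
subsumption; other relations are ignored.  IC monotonicity along
child→parent edges is asserted after scoring.

For each bicluster, the intra sample is SimGIC over unordered annotated
gene pairs within it, and the inter sample pairs its annotated genes with
annotated genes of the other biclusters at the same level (excluding its
own).  Unannotated genes are excluded rather than scored 0 — scoring them
0 would deflate the intra mean of sparsely annotated modules — and the
number of annotated genes is reported so users can judge support.  Samples
larger than 2,000 pairs are uniformly subsampled with a seeded generator.
The test is a one-tailed two-sample Welch t-test (unequal variances) of
H1: μ0(C) > μ(L, C); Welch is the robust default since nothing guarantees
equal variances between intra and inter samples.  Degenerate inputs
(either sample < 2, or two zero-variance samples with equal means) give
p = 1; zero-variance samples with the intra mean strictly larger give
p = 0.  No multiple-testing correction is applied; p-values are a ranking
device, and significant-count reporting uses 0.05.

## Synthetic generators and what they (do not) show

All generators are pure functions of seed and parameters.

* `planted_matrix`: in-module scores U(0.7, 1.0), background U(0, 0.2)
  with values below 0.05 dropped (keeping the background sparse like
  genome-wide prediction tables); the default layout is 4 disjoint modules
  of 10 miRNAs × 40 genes, and `overlap_fraction` chains a share of each
  module's miRNAs into the next.  The signal/noise gap is explicit and
  generous, so recovery tests certify the machinery, not robustness to
  marginally separated modules.
* `pu_scores`: per-dimension uniform class-conditionals of width 0.4
  separated by a shift (default 0.6, making supports disjoint), prior 0.5,
  SCAR labeling with c = 0.5 at n = 10,000.  Real prediction scores are
  neither uniform nor independent across algorithms; the fixture verifies
  SCAR-consistent estimation, not performance on real score marginals.
* `toy_ontology`: a random tree of bounded depth; coherent gene groups
  share a dedicated maximal-depth term (rare, hence high-IC) plus random
  terms; other genes are annotated at random.  Real GO is a multi-parent
  DAG with very uneven annotation depth — the toy captures only the
  IC/closure structure the ranking relies on.

Passing tests therefore demonstrate correctness of the algorithms under
their own assumptions; they do not certify biological performance on
production-scale prediction data, which requires the real upstream
databases and full GO.

## Problem sizes and runtime

Validation runs use the sizes above (40×160 matrices over 10 seeds,
n = 10,000 PU examples over 10 seeds, 200 null biclusters of 20 genes,
8×8 matrices for the oracle comparison).  The full test suite completes in
well under a minute on one CPU and `scripts/acceptance.py` in about ten
seconds; these sizes were chosen as the smallest at which the targeted
statistical properties (parameter recovery bands, null calibration) are
stable across seeds.

## Known limitations

* The greedy aggregation is locally optimal per step; no beam search or
  alternative merge orders are attempted.
* Coverage evaluation treats the validated-gene denominator as the full
  validated set, so validated genes missing from the scored set make high
  coverage levels "not reachable" rather than silently shrinking the
  target.
* Gene identity is the case-normalized official symbol string; no alias
  or cross-database resolution is performed.
* Intra/inter similarity samples share genes, so the t-test's independence
  assumption is approximate; calibration under exchangeable annotations is
  verified empirically (null significant fraction ≈ 0.05, KS ≤ 0.1) rather
  than guaranteed analytically.
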