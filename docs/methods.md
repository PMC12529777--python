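# Methods

This note documents the models and procedures implemented in `splitshift`,
the defaults and why they were chosen, what the synthetic benchmark does and
does not emulate, and the numerical decisions that affect results.

## Splitting model

A data set is a list of standardized molecules with binary activity labels.
Every splitter partitions the record ids into an **ID pool** and an **OOD
test set** (default OOD fraction 0.2); only the Lo-Hi splitter may also
*remove* molecules. Record-level splitters draw exactly ⌈0.2·N⌉ ids;
group-level splitters (scaffold, cluster) assign whole groups in order until
the OOD set first reaches the target, so their OOD fraction lands near, not
exactly on, 0.2 — whole-group assignment is what guarantees that no scaffold
or cluster straddles the partition.

Determinism contract: `molweight`, `molweight-reverse`, `logp`, and `lohi`
are pure functions of the data; all other splitters take a seed and are
bit-reproducible given it.

### Cluster splitters

Fingerprints are ECFP4 (Morgan radius 2), 2048 bits for cluster and
property splitters, 1024 bits for the similarity-graph splitters. K-means
and max-dissimilarity operate in a *reference-distance space*: each molecule
is embedded as its vector of Tanimoto distances to 512 randomly chosen
reference molecules, turning binary fingerprints into a continuous
representation where Euclidean K-means is meaningful. Cluster count
defaults to 10 — commensurate with the chemotype granularity the splits are
meant to resolve; both it and the reference count are configurable. The
UMAP splitter embeds fingerprints to 2-D (15 neighbors, min_dist 0.1,
Jaccard metric), clusters the embedding with Ward agglomeration (10
clusters), and fills the OOD set farthest-cluster-first from the global
embedding centroid. "Maximize distributional shift" is not a uniquely
defined rule; distance-from-centroid ordering is this package's
operationalization and is recorded in each split's provenance.

### Similarity-disconnection integer programs

**Lo-Hi** builds the similarity graph (edge when Tanimoto > 0.4), optionally
coarsens it with Butina sphere-exclusion clustering at the same threshold,
and solves: minimize removed weight subject to (i) no edge joining an ID
unit to an OOD unit and (ii) OOD weight within ±10% (relative) of
0.2 × surviving weight, relaxed in +5% steps if infeasible. The audit
invariant — no OOD molecule with similarity > 0.4 to any ID molecule — is
implied by (i) and verified exhaustively in the tests. Coarsening is enabled
above 500 molecules: within-chemotype similarity graphs are dense enough
that the node-level program stops being worth its cost there, and the
cluster-level program preserves the audit invariant exactly (a cluster-level
edge witnesses every molecule-level cross edge). The tolerance is read as
*relative* to the OOD target: an absolute ±10% band would let the solver
reach a trivial zero-removal solution at a 10% OOD share.

**DataSAIL-style S1 cold split** preclusters molecules with spectral
clustering on the Tanimoto similarity matrix (50 clusters), then assigns
whole clusters to ID/OOD minimizing the total similarity between clusters
on opposite sides, under the same relative size band. This balanced min-cut
has a weak LP relaxation: the solver proves optimality slowly even when it
finds the optimum early. Instances with ≤ 15 clusters are solved exactly;
larger ones accept a 15% relative MIP gap and a 60 s time limit (the
incumbent is used, with a warning, if the limit is hit). Both programs run
on the HiGHS solver via `scipy.optimize.milp`; a documented greedy
edge-cut fallback exists for environments without an ILP solver and
preserves the audit invariant, not optimality.

## Label-shift-controlled workflow

OOD hardness should come from covariate shift, not from a changed class
prior. For stochastic splitters, candidates are generated under seeds
`base_seed + i` (auditable), and a candidate is accepted when
|active%(ID) − active%(OOD)| is *strictly below* the current threshold.
Thresholds start at 1 percentage point and relax by 1 pp up to 10 pp; if the
candidate budget (100) is exhausted the same candidates are re-filtered at
the relaxed threshold, preserving candidate order. Deterministic splitters
return their single split with its label shift recorded as-is. Accepted ID
pools are subdivided 72/8/20 (train / ID-validation / ID-test) by per-class
largest-remainder allocation, which keeps each subset's active fraction
within one record of the pool's. The threshold schedule values are package
defaults, chosen so that typical cluster splits on balanced data qualify
within one or two relaxations.

## Distances

**k-NN set distance** (k = 5): for each OOD molecule, the mean distance to
its k nearest training molecules; the split's hardness score is the median
over OOD molecules. With Tanimoto distance this is bounded in [0, 1];
k is clipped to the training size with a warning.

**Tree Mover Distance** compares node-attributed graphs via their multisets
of depth-L message-passing computation trees. The distance between two
trees is the L1 difference of root features plus a weighted optimal
transport between their child-subtree multisets, padded with blank
(zero-feature) trees to equal size; the graph-level value is the transport
between the two node-tree multisets, padded likewise. All transports are
solved exactly as balanced assignments (direct permutation enumeration for
multisets of ≤ 5, Hungarian algorithm above). Defaults: depth L = 3, unit
level weights, L1 feature norm. Bond features, when present, are appended
to the child node's feature vector during unrolling — the graphs here carry
bond information and the node-only formulation would discard it. The
implementation is validated against an exhaustive-permutation oracle on all
graphs with ≤ 4 nodes. Cost is quadratic in node count per pair and
quadratic in set sizes per profile, so TMD profiles at benchmark scale are
computed on seed-subsampled sets (15 OOD × 80 train in the acceptance
script; sizes chosen to keep a profile under a minute per splitter).

## Evaluation harness

Adapters wrap scikit-learn/XGBoost estimators behind a two-method contract
(`fit`, `predict_scores` in [0, 1]). Hyperparameters are fixed per adapter —
no per-split tuning — so that ID/OOD differences reflect the data shift.
Margin classifiers map decision values through a sigmoid (rank-preserving;
keeps the 0.5 accuracy threshold at the decision boundary). The reference
adapters are a 300-tree random forest, a linear SVM (C = 1), and XGBoost
(300 trees, depth 6, η = 0.1) on ECFP4(2048). The correlation-study pool
adds shallow variants, logistic regression, extremely randomized trees, and
k-NN — eight fixed models spanning weak to strong, enough spread for a
meaningful ID-vs-OOD regression. Top-N ranking ties break by record id.

## Synthetic benchmark

The generator decorates 10 ring-system templates (benzene through biphenyl,
spanning a molecular-weight and logP range) with 1–3 substituents from a
15-fragment alphabet. Activity is defined *structurally*: each template is
paired with one of four pharmacophore groups (sulfonamide, carboxylic acid,
trifluoromethyl, nitrile), and a molecule is active exactly when some
template's ring system carries its paired group; the same groups also appear
as decoys on non-matching templates. Quota sampling fixes the pre-noise
active count, and label noise flips exactly ε of each class (default
ε = 0.1), keeping the realized active fraction on the 45% target by
construction. Defaults (2,000 molecules, 30–70% active envelope, shared
scaffolds) emulate the statistical envelope of curated public bioactivity
classification sets at desk scale.

Design consequences, verified by the test suite:

- activity depends on the template × group interaction, so holding out whole
  chemotypes (cluster splits) removes label-relevant feature regions and
  produces genuine positive ΔROC-AUC, while the per-template active fraction
  stays near the global target — covariate shift without label shift;
- ring-bearing substituents fragment Bemis-Murcko scaffolds within a
  chemotype, so scaffold splits are harder than random but easier than
  cluster splits, reproducing the qualitative hardness ordering
  random < scaffold < {k-means, UMAP, Lo-Hi} on both the 5-NN distance and
  the model gap;
- with label noise 0 the labels are exactly reproducible by substructure
  matching, which the tests use as an oracle.

What the generator does **not** emulate: realistic medicinal-chemistry
property distributions, activity cliffs, assay noise structure, scaffold
hopping, or data set sizes beyond a few thousand. Passing the suite shows
the pipeline's mechanics and orderings are correct under controlled
conditions; it does not certify effect sizes on real screening data.

## Numerical choices and degenerate inputs

- Tanimoto of two all-zero fingerprints is defined as 1.0 (identical
  objects). Similarity matrices accumulate integer popcounts in float32 but
  divide in float64, so exact ratios (e.g. 10/25) compare exactly against
  thresholds.
- Duplicate records with conflicting labels are removed entirely — a binary
  task cannot keep contradictory labels.
- Standardization order: largest organic fragment → charge neutralization →
  tautomer canonicalization. Charge neutralization stands in for
  protonation-state correction at the configured pH; RDKit has no
  pH-dependent protonation model, and the neutral-form convention is applied
  uniformly. Unparseable SMILES become rejection records, never silent
  drops.
- Property-sort ties break by record id; a tie group spanning the 20%
  boundary is split by id order.
- Sorting-based and ILP splitters are deterministic given the solver;
  stochastic splitters derive all randomness from their seed argument.
- Pairwise-similarity splitters refuse N > 25,000 (quadratic memory).

## Known limitations

- The UMAP splitter's shift-maximization rule and the cluster counts are
  package operationalizations of under-specified procedures; both are
  configurable and recorded in split provenance.
- The DataSAIL-style split is the one-dimensional similarity variant only;
  two-axis (drug–target) cold splits are out of scope.
- GNN adapters are an extension point (the adapter contract), not shipped
  models; the evaluation results here are for classical fingerprint models.
- Large-instance cold splits may return a time-limited incumbent rather
  than a proven optimum (always flagged by a warning).
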