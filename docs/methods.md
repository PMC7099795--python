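# Methods

## The model

`rflda` scores candidate lncRNA–disease associations (LDAs) with a random
forest trained on heterogeneous association data. The inputs are three
binary relations over shared entity axes — lncRNA–disease associations
(LD), miRNA–disease associations (MD) and lncRNA–miRNA interactions (LM) —
plus an `IS_A` disease ontology. From these the package derives two
similarity matrices and represents each lncRNA–disease pair `(l, d)` by the
concatenation

    F(l, d) = LL[l, :] ⊕ LD[l, :] ⊕ LM[l, :] ⊕ LD[:, d] ⊕ DD[d, :] ⊕ MD[:, d]

of width `2·(n_L + n_D + n_M)` — at the reference scale of 240 lncRNAs,
412 diseases and 495 miRNAs, a 2294-dimensional vector split into two
1147-dimensional entity halves. Known associations are positives (label 1),
an equal number of uniformly sampled unconfirmed pairs are negatives
(label 0), and a regression forest's mean tree output is the association
score in [0, 1].

### Disease semantic similarity (DD)

A disease `D` is represented by the DAG of itself plus its transitive
`IS_A` ancestors `S(D)`. Each node contributes

    DC_D(D) = 1,   DC_D(d) = max{ Δ · DC_D(d') : d' a child of d within S(D) },

with attenuation Δ = 0.5 by default (configurable, must lie in (0, 1]).
The recursion is anchored at `D` and memoized over the reversed edges; for
a uniform Δ it evaluates to Δ raised to the shortest `IS_A` distance from
`D`, which is also the independent oracle the tests check against. The
semantic value is `DV(D) = Σ_{d∈S(D)} DC_D(d)` and the similarity of two
diseases is the contribution mass of their shared nodes:

    DS(i, j) = Σ_{d ∈ S(i)∩S(j)} (DC_i(d) + DC_j(d)) / (DV(i) + DV(j)).

`DS` is symmetric, 1 on the diagonal and bounded by 1 because the shared
node set is a subset of each DAG. Diseases absent from the ontology get
the single-node self DAG: self-similarity 1, cross-similarity 0 — this
keeps the matrix axes intact without inventing structure. Values are
clamped to [0, 1] after computation to absorb boundary rounding.

### lncRNA functional similarity (LL)

Two lncRNAs are compared through their associated-disease sets `DG(a)`,
`DG(b)` by the best-match average

    LS(a, b) = ( Σ_i max_j DS(a_i, b_j) + Σ_j max_i DS(b_j, a_i) ) / (m + n).

An lncRNA with no known associations has an undefined profile; its
similarity (including its diagonal entry) is defined as 0 and logged, so
the full LL matrix stays dense rather than erroring. Ties inside the max
need no tie-break (it is a max over reals).

### Normalization and pruning

Features are min–max scaled per column; constant columns map to 0. The
scaling statistics are fitted on the training rows only and re-applied to
held-out rows (clipped to [0, 1]), which avoids train/test contamination;
a `paper_exact` normalization mode computes the statistics over train and
test jointly, as the original protocol literally states. Features that
are zero in every training row are dropped, and the removal mask is
re-applied to any later sample matrix.

### Self-association leakage

`F(l, d)` contains the pair's own cell `LD(l, d)` twice (once in each LD
block). With labels defined from LD this is label leakage. The default
mode (`mask_self=True`) zeroes both occurrences per row; the faithful
mode keeps them for comparison. Both are exposed on the model and the CLI
(`--mode masked|paper_exact`).

### Feature selection

Variable importance is Breiman's out-of-bag permutation importance,
implemented per tree: each regression tree is grown on a bootstrap
sample, its out-of-bag rows are scored before and after permuting one
feature column, and the feature's score is the mean error increase over
trees. Features a tree never splits on contribute exactly zero (and are
skipped, which also makes the computation linear in the number of *used*
features). The default error is out-of-bag MSE — for 0/1 targets this is
monotonically related to the accuracy decrement at a 0.5 threshold — and
a `classification` option measures the accuracy decrement literally.
Scores are averaged over 10 independently seeded runs (run *r* uses
`base_seed + r`); features are ranked by mean score with ties broken by
feature id, so the order is a deterministic total order. The operating
size `k` defaults to 300 and can instead be chosen by sweeping ranking
prefixes (e.g. the 39-point grid 50:1950:50) through stratified 10-fold
CV, counting a held-out sample correct when its regression score
thresholded at 0.5 (the midpoint of the label coding) matches its label.
`mtry` follows the p/3 rule (rounded down, minimum 1) at every stage and
every k unless pinned; `ntree` is 500.

## Evaluation protocol

Cross-validation divides positives and negatives each into `folds`
near-equal shuffled parts (2697 positives over 5 folds gives parts of
540/540/539/539/539). Each fold trains on the remaining parts and scores
the held-out positives against every unconfirmed pair; the repetition's
sampled training negatives are excluded from that pool by default
(they were trained on as 0), with an `include_trained_negatives` switch
for the literal protocol. The experiment is repeated (default 10 times)
with freshly sampled negatives and fold assignments, seeds
`base_seed + repetition`. AUC is the trapezoidal area under the
tie-grouped ROC curve — identical, to machine precision, to the
pairwise-ordering statistic — and AUPR uses step-wise integration
(precision held constant over each recall increment), matching average
precision. Both fold-level and repetition-level standard deviations are
reported, since either could be meant by a "±" on a summary value.

Case studies hold out one disease entirely: its LD column is zeroed, the
LL matrix is *recomputed* from the masked LD (LL is derived from LD, so
this matters), training negatives are drawn from other diseases' pairs
only, and every lncRNA is then scored against the held-out disease.

## The synthetic benchmark

The generator emulates the shape of the real inputs, not their content:
entities are assigned to contiguous clusters; associations are Bernoulli
draws at `within_cluster_assoc_prob` inside clusters and
`background_assoc_prob` elsewhere; the ontology gives each cluster's
diseases a shared low ancestor (depth `dag_depth`, with occasional second
parents) while cross-cluster diseases share only the root. A 20% holdout
of the within-cluster LD positives is zeroed and recorded as planted
truth. Defaults: 60 lncRNAs × 40 diseases × 50 miRNAs, 4 clusters,
within-cluster probability 0.35, background 0.02, depth 3. The background
rate mirrors the real data's ~2–3% density; the within-cluster rate gives
each cluster enough observed positives (~40) for a 500-tree forest to
learn from at sub-minute test runtimes. The real 240×412×495 scale is a
configuration choice, not a test default.

**What recovery can and cannot measure.** Association draws are
independent given cluster membership, so a planted hold-out pair is
statistically exchangeable with an unlabelled *within*-cluster pair: no
scorer, however good, can separate those two groups, and ranking truth
against all unlabelled pairs hits a structural AUC ceiling (~0.90 at the
defaults) set by that tie mass. Recovery is therefore evaluated against
the benchmark's *background* pairs — cross-cluster pairs with no observed
association, the class actually generated as noise — exposed as
`synthetic.background_pairs`. Under the default conditions (500 trees,
5-fold CV, 3 repetitions) the model reaches recovery AUC ≈ 0.94 against a
shuffled-label null of ≈ 0.5. The benchmark does not mimic real ontology
topology, heavy-tailed node degrees, or curation biases, so passing it
shows the pipeline recovers planted block structure — not that real-data
headline numbers transfer.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeds carried in
  the configuration; identical configurations reproduce rankings and
  matrices bitwise. Forests use a single thread for determinism.
- Similarities are clamped to [0, 1]; prediction tables order by score
  descending with lncRNA-name tie-break so output files are byte-stable.
- The LM matrix's miRNA axis is validated against the MD matrix's miRNA
  axis rather than a hard-coded count (published descriptions of such
  datasets occasionally disagree on the miRNA total; the axes themselves
  are authoritative).
- The all-zero-column rule reports whatever count results on the data at
  hand; no fixed "preserved feature" count is assumed.
- Whether importance runs should re-draw training negatives is left as an
  option (`fit` uses one fixed training set per call by default).

## Limitations

- Negative labels are unconfirmed pairs, not verified non-associations;
  scores are rankings, not calibrated probabilities.
- The per-tree permutation importance is O(trees × used-features × OOB
  rows) and is the pipeline's dominant cost at full scale.
- Out-of-ontology diseases contribute no semantic signal; if many
  diseases are unmapped, DD degenerates toward the identity.
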