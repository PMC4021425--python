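# Methods

This note documents the models, conventions and numerical choices behind
`treestrat`, in the order data flows through the pipeline.

## Synthetic data: the multispecies coalescent simulator

Gene trees are simulated branch-by-branch down a rooted, ultrametric species
tree whose edge lengths are in **coalescent units** (generations / 2N). Within
a species-tree branch carrying *j* lineages, waiting times to the next
coalescence are exponential with rate C(j,2) per unit; lineages that fail to
coalesce pass to the parent branch, and the root branch runs until a single
lineage remains. Sequences then evolve along the gene tree under a reversible
substitution model (HKY with κ = 2 by default; GTR available), with the root
sequence drawn from the stationary frequencies and independent columns. A
single **scale** factor converts coalescent units to expected substitutions
per site, so the amount of incomplete lineage sorting (controlled by internal
branch lengths) and the sequence divergence (controlled by scale) are
independently tunable. No rate heterogeneity across sites is applied by
default; an optional lognormal per-locus rate multiplier exists but is off
(σ = 0).

Missing data are modeled by deleting each (individual, locus) record
independently with probability `missingness`, re-drawing any deletion pattern
that would leave a species with no sequence at a locus (the analysis assumes
every species is represented everywhere). The block structure of real
missingness — individuals failing for whole primer sets — is **not** modeled;
passing tests therefore say nothing about non-random missingness.

Presets (the study conditions; all values chosen once, a priori):

| preset | species | individuals | loci × bp | ingroup internals (cu) | scale | missing |
|---|---|---|---|---|---|---|
| `pine_full` | 8 ingroup + 3 outgroup (sister clade) | 14/ingroup, 3/outgroup (121) | 121 × 390 (~47 kb) | 0.4 | 0.01 | 0.15 |
| `pine_small` | as above | 3/1 (27) | 20 × 200 | 0.4 | 0.01 | 0.10 |
| `high_ils` | 8 + 1 | 2/1 | 15 × 300 | 0.15 | 0.01 | 0 |
| `low_ils` | 6 + 1 | 2/1 | 30 × 300 | ≥ 5 | 0.004 | 0 |

Outgroups diverge ≥ 10 coalescent units deep so that outgroup monophyly in
gene trees is near-certain and rooting is reliable. `pine_full` emulates the
scale of the motivating conifer dataset; `pine_small` is the same design at
desk scale. Per-locus lengths are uniform (no empirical length distribution
is modeled). Statistical checks in the test suite run at reduced problem
sizes — e.g. recovery is tested on `low_ils` (6 ingroup taxa, 30 loci, B = 1,
100 seeded runs) and the balance comparison on 50 `high_ils` replicates of
15 gene trees — chosen so each check carries enough replication to be
informative while the whole suite stays quick.

## Derived datasets

`select_Ds` maximizes the per-locus total overlap n(A) = Σ n(x,y), breaking
ties by total differences d(A) = Σ d(x,y), then uniformly at random from the
seeded stream (tie randomization is per locus). The search is exhaustive over
the product of per-species choices when that product is ≤ 10⁶ and otherwise
uses coordinate ascent with 8 random restarts — exactness where it is
testable, a heuristic at full scale where the product (e.g. 14⁸) is
infeasible.

Both `'-'` (gap) and `'?'` (missing) are excluded identically from overlap
counts; no other ambiguity codes are accepted. The zero-distance filters
exempt distinct-outgroup pairs. A locus where some species pair has zero
pooled overlap has an undefined per-locus distance and is dropped from Dp,0
with a logged warning, since the distance ratio is otherwise division by
zero.

Species distances accumulate integer (d, n) pairs and divide once at the
end; this makes the identity "pooled weighted average = concatenated
p-distance" exact, not approximate, and bootstrap resampling simply re-adds
per-locus integer tables (a locus drawn twice counts twice).

## Gene trees

* **NJ** is Saitou–Nei agglomeration (via scikit-bio) with negative branch
  estimates clamped to zero; three taxa give the unique star resolution.
* **MP** uses Fitch parsimony with gaps/missing as fully ambiguous states.
  The search is exact branch-and-bound over unrooted topologies up to 8 taxa
  (co-optimal trees drawn uniformly from the seeded stream); beyond that an
  NNI hill-climb starts from the NJ tree. The exact bound was set where the
  pure-Python search stays fast; the pipeline's 9-taxon alignments use the
  hill-climb. MP branch lengths are Fitch changes per branch per site from a
  deterministic state resolution — a rough surrogate used only where a
  downstream method needs lengths.
* **ML** maximizes GTR likelihood by Felsenstein pruning over compressed
  site patterns: base frequencies fixed at empirical counts (+1
  pseudocount), exchangeabilities optimized by L-BFGS-B on a log scale,
  branch lengths by bounded scalar optimization (tolerance 1e-6), and NNI
  moves accepted when the log-likelihood improves by > 1e-8 (candidates are
  screened with a cheap branch re-optimization; the winner gets a full
  sweep). All-identical alignments return the NJ star resolution with zero
  lengths and a warning. No per-site rate heterogeneity.
* **M** is NJ applied to the pooled (concatenation-type strategies) or
  per-locus (consensus-type strategies) species distance matrix; its leaves
  are species, so no within-species gene-tree structure is inferred.

Strategy scope: before inference, data are restricted to the 8 ingroup
species plus the strategy's single outgroup; the other outgroups play no
role downstream for that strategy.

## Species-tree methods

* **Concatenation** applies the strategy's gene-tree method to the
  concatenated super-locus, roots with the outgroup, and prunes it.
* **SMRT** infers all C(m,3) rooted triples from 4-taxon restrictions of the
  super-locus (for MP, by exhaustive scoring of the three quartet
  topologies; ties mean the triple is dropped) and assembles them with a
  modified-mincut supertree: Aho's BUILD recursion on the triple graph with
  edge weights equal to the supporting triple count; when the graph is
  connected, edges supported by **all** relevant triples are protected from
  cutting, every edge lying in some minimum-weight cut is removed (an edge
  is in some minimum cut iff the minimum cut separating its endpoints equals
  the global minimum), and the recursion continues on the components.
  Symmetric conflicts therefore yield polytomies.
* **STEAC** averages pairwise coalescence times — half the leaf-to-leaf path
  length, exact for ultrametric trees — over gene trees and applies NJ; the
  outgroup is included in the averaging and pruned after rooting.
* **STAR** assigns the root of each rooted gene tree rank = number of
  species and every internal node one less than its ancestor (polytomy
  children share the decremented rank); the pair entry is the rank of the
  connecting node, averaged over trees, followed by NJ. The matrix uses the
  rank itself; NJ topology is invariant to uniform scaling.
* **RTC** pools the rooted triples displayed by all gene trees with
  multiplicity weights and runs triplet puzzling: for each of P random
  insertion orders (default P = 100) taxa are inserted at the placement
  maximizing the weighted agreement of triples involving the new taxon (ties
  random from the seeded stream); the majority-rule consensus of the P
  puzzled trees is returned.
* **MDC** minimizes the deep-coalescence cost: for each species-tree branch
  with clade A, lineages exiting = |A| minus the number of gene-tree
  coalescences whose cluster is inside A, and the cost sums (lineages − 1)
  over branches. The default search is exhaustive over all (2m−3)!! rooted
  binary topologies for m ≤ 8 (135,135 at m = 8; the enumeration is cached
  and per-candidate costs are computed by a subset-sum transform of the
  gene-tree cluster counts, so a full scan is milliseconds). The heuristic
  mode (m > 8) runs rooted-NNI descent from a randomly refined greedy
  consensus of the gene-tree clades. Co-optimal topologies are drawn
  uniformly from the seeded stream.
* **Greedy consensus** accepts clades in decreasing count order whenever
  compatible with the accepted set; ties break deterministically by smaller
  bitmask.

## Bootstrap engine

Replicates draw L loci with replacement; sites within loci are never
resampled (short, conserved loci would otherwise lose their variation).
Gene trees are re-inferred from the resampled loci per replicate rather than
resampled from precomputed trees, because tie-breaking randomization should
be independent across replicates. A replicate whose inference fails (an
undefined distance after resampling) is re-drawn, up to three attempts, so
every replicate keeps exactly L loci. Non-binary estimates contribute only
their resolved clades to the count matrix; for fully binary estimates each
row of **S** sums to (m−2)·B.

All randomness flows from a single integer seed through
`numpy.random.Generator` streams (one spawned child per strategy in the
CLI), making runs bitwise reproducible.

## Multivariate analysis

PCA centers the clade-count columns but does not variance-scale them (counts
share the common 0..B scale); variance fractions come from the singular
values. MDS is classical principal-coordinate scaling (double-centering of
squared distances), not stress minimization. The strategy×strategy distance
is the mean rooted Robinson–Foulds distance — the symmetric difference of
non-trivial clade sets — over all B×B cross pairs, computed exactly up to
10⁶ pairs and by seeded subsampling above. Procrustes superimposition allows
scaling, rotation, reflection and translation; the dissimilarity is the
residual sum of squares normalized by the centered scatter of the target and
lies in [0, 1]. Ward clustering is the minimum-variance (squared-Euclidean)
criterion via SciPy's linkage; K-means is Lloyd's algorithm, best of R
random restarts (10⁴ at full scale, ~10²  in tests) plus one restart seeded by
splitting the widest cluster of the best (K−1)-solution, which enforces
WSS(K) ≤ WSS(K−1). Pearson correlations between strategies are restricted to
clades nonzero in both rows. Clade flow from strategy i to j is the
count-weighted fraction of i's inferred clade instances absent from j's
observed set (a distinct-clade variant is available behind a flag).

Exact invariances worth noting: removing strategies that sit at the centroid
of **S** leaves the Procrustes influence at zero; removing one copy of a
duplicated strategy does *not* (it reweights the covariance), and the tests
assert only a small bound for that case.

## Known limitations

- The simulator draws missingness uniformly at random and loci at one length.
- MP beyond 8 taxa and MDC beyond 8 species are local searches without
  optimality guarantees.
- ML assumes no rate heterogeneity and fixes frequencies at empirical
  counts; model misspecification on real data is untested.
- The pipeline assumes usable outgroups (deep divergence, monophyletic);
  rooting failures on shallow outgroups are not handled specially.
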