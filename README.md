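# treestrat

Evaluation of **two-stage species-tree inference strategies** on multilocus
sequence data.

When gene trees disagree with the species tree — as they do under high
incomplete lineage sorting (ILS) in recently radiated groups such as North
American white pines — a species tree can be estimated in two stages: infer a
gene tree per locus, then combine the gene trees. A *strategy* is a triple

> (species-tree method) × (gene-tree method) × (outgroup choice)

with six species-tree methods (Concatenation, SMRT, STEAC, STAR, RTC, MDC),
four gene-tree methods (maximum likelihood, maximum parsimony,
neighbor-joining, and the multi-individual distance method "M"), and a choice
among outgroup species — 72 strategies for a design with three outgroups.
`treestrat` runs every strategy through an across-loci bootstrap, counts the
clades its *B* species-tree estimates display, and compares strategies through
the resulting strategies × clades count matrix **S**.

## What is implemented

- **Derived datasets.** From a multilocus dataset *D* with individuals
  *x, y* and per-pair overlap *n(x,y)* (non-gap, non-missing shared columns)
  and differences *d(x,y)*:
  - **Ds** — per locus, the one-individual-per-species subset maximizing total
    overlap Σ *n(x,y)*, ties broken by total differences Σ *d(x,y)*, then at
    random;
  - **Ds,0** — the Ds loci with *d(x,y)* > 0 for every cross-species pair
    (outgroup–outgroup pairs exempt);
  - **Dp** — the full dataset;
  - **Dp,0** — the loci whose per-locus species *p*-distance
    P<sup>ℓ</sup><sub>ij</sub> = Σd / Σn is positive for every such pair.
  The Ds,0 locus set is provably contained in the Dp,0 locus set.
- **Species-level distances.** The pooled matrix
  P<sup>all</sup><sub>ij</sub> = Σ<sub>loci</sub>Σ<sub>pairs</sub> d /
  Σ<sub>loci</sub>Σ<sub>pairs</sub> n (a weighted average equal to the
  p-distance on a concatenated alignment, computed in exact integer
  arithmetic) and its per-locus analogue P<sup>ℓ</sup>; NJ on these matrices
  is the "M" gene-tree method.
- **Gene trees.** Neighbor-joining on p-distances, Fitch maximum parsimony
  (exact branch-and-bound at small sizes), GTR maximum likelihood
  (Felsenstein pruning, NNI search, empirical base frequencies), outgroup
  rooting.
- **Species trees.** Concatenation; SMRT (all C(m,3) rooted triples from the
  concatenated alignment assembled by a modified-mincut supertree); STEAC
  (NJ on mean coalescence times); STAR (NJ on mean coalescence ranks); RTC
  (rooted-triple consensus via triplet puzzling); MDC (minimize deep
  coalescences, exhaustive over all rooted topologies up to eight taxa);
  greedy consensus.
- **Bootstrap engine.** Loci resampled with replacement (sites never
  resampled), gene trees re-inferred per replicate, clade counts assembled
  into **S**.
- **Multivariate comparison.** Clade-size/balance statistics, PCA of **S**,
  classical MDS of mean Robinson–Foulds distances between bootstrap tree
  sets, Procrustes influence of strategy subsets, Ward and K-means
  clustering, nonzero-restricted correlation, clade flow, and representative
  greedy-consensus topologies.
- **Synthetic data.** A multispecies-coalescent simulator (exponential
  coalescence at rate C(j,2) per branch, HKY/GTR finite-sites sequences,
  per-individual missingness) with presets emulating the pine study design:
  11 species, ~120 individuals, 121 loci, ~47 kb.

## Worked example

```python
import numpy as np
from treestrat.simulate import generate_pine_like_dataset
from treestrat.datasets import build_all_roles
from treestrat.bootstrap import (StrategyDescriptor, run_strategy,
                                 collect_clades, build_clade_matrix)
from treestrat.multivariate import clade_size_stats, nonzero_correlation

dataset, truth = generate_pine_like_dataset("pine_small", seed=7)
roles = build_all_roles(dataset, np.random.default_rng(7))

B, rows = 20, []
for method in ["star", "mdc"]:
    strat = StrategyDescriptor(method, "nj", "out1")
    trees = run_strategy(strat, roles, B, np.random.default_rng(1))
    rows.append((strat, collect_clades(trees)))

S = build_clade_matrix(rows, B, dataset.ingroup)
for strat, counts in rows:
    _, mean, se = clade_size_stats(counts)
    print(f"{strat.label}: mean clade size {mean:.2f} +/- {se:.2f}")
print(f"correlation on shared clades: {nonzero_correlation(S, 0, 1):.2f}")
```

prints

```
STAR+NJ+out1: mean clade size 2.85 +/- 0.09
MDC+NJ+out1: mean clade size 2.68 +/- 0.09
correlation on shared clades: 0.79
```

Each of the 20 bootstrap species-tree estimates of an 8-ingroup dataset
displays six non-trivial clades; the mean clade size measures topological
balance (a maximally balanced 8-taxon tree scores 2.67, a caterpillar 4.5).
Here MDC infers more balanced trees than STAR — its known tendency — and the
two topology-based strategies agree strongly (r = 0.79) on the clades they
both recover.

The same pipeline is scriptable from the shell:

```bash
treestrat simulate --preset pine_small --seed 3 --out-dir data
treestrat build-datasets --data-dir data --taxon-map data/taxon_map.tsv --seed 3 --out-dir roles
treestrat bootstrap --data-dir data --taxon-map data/taxon_map.tsv --config cfg.yaml --out-dir boot
treestrat compare --matrix boot/clade_matrix.tsv --out-dir cmp
```

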