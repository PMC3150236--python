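# multinet

Multiplicity-based network organization of somatic-mutation catalogs.

## The problem

Curated somatic-mutation resources record, for hundreds of thousands of tumor
samples, which genes carry mutations.  Organizing that flood of gene-level
observations into clinically meaningful structure is hard: per-gene mutation
rates are dominated by measurement intensity and by cancer-specific hotspots,
and pathway-level grouping is ambiguous because pathways overlap.  `multinet`
implements an alternative organizing principle: **multiplicity** — how broadly
a gene's mutations recur *across* cancer types — measured on networks built
from the catalog itself.  Genes that are significantly mutated in many of the
same cancers are candidate *drivers* of tumor progression; genes mutated in a
single cancer type are more likely *passengers*.

## The method

Starting from a catalog of per-(gene, cancer-type) mutant-sample counts with
equal-size cohorts (cancer types below the cohort size are dropped; the rest
are down-sampled without replacement):

1. **Two-mode network.**  Gene *g* is linked to cancer *i* when its mutation
   rate in *i* beats its pooled rate across all types, by a 1-df chi-square
   goodness-of-fit test over the cells {mutant, non-mutant} at *p* < α
   (default 0.05), enrichment only.
2. **One-mode projection.**  Two genes are linked with multiplicity
   |C′<sub>gh</sub>| = the number of cancers in which both are significantly
   mutated (symmetrically for cancers: the number of shared genes).  A node's
   **maximum multiplicity** (*m*-slice value) is the largest multiplicity
   among its links — the systemic-occurrence score.
3. **Layout.**  The one-mode network is embedded in the plane by minimizing
   the Kamada-Kawai spring energy
   E = Σ<sub>i&lt;j</sub> (k<sub>ij</sub>/2)(‖p<sub>i</sub>−p<sub>j</sub>‖−l<sub>ij</sub>)²
   with rest lengths proportional to shortest-path distances over link
   dissimilarities 1/multiplicity.
4. **3D embedding.**  Maximum multiplicity becomes the z axis; coordinates are
   normalized to the unit cube.
5. **Clustering.**  Ward's minimum-variance agglomeration on the 3D Euclidean
   distances; the tree is cut at a dissimilarity threshold or into *k*
   clusters.
6. **Evaluation.**  Genes inherit their cluster's mean maximum multiplicity
   (normalized by the top cluster); the score is swept against a causal-gene
   list to give a ROC curve.  Four feature spaces are compared: 3D, maximum
   multiplicity alone, the 2D plane alone, and mutation rate alone.

Cancer-cancer links can optionally be re-weighted so each endpoint contributes
the inverse of its mutated-gene count (a cancer with 10 associated genes
contributes 1/10; one with 299 contributes 1/299), which reduces the pull of
mutation-heavy cancers on the layout.

## Worked example

No external data is needed — the package ships a synthetic-catalog generator
with planted ground truth (10 cancer types × 500 tumors; 20 systemic driver
genes mutated at rate 0.3 in 5 cancers each; 200 cancer-specific passenger
genes at rate 0.1; background 0.01):

```python
from multinet import FixtureConfig, generate_catalog, MultiplicityPipeline

catalog, drivers = generate_catalog(FixtureConfig(seed=7))
pipe = MultiplicityPipeline(n_clusters=10, seed=7).fit(catalog, drivers)
print("two-mode:", len(pipe.two_mode_.genes), "genes x",
      len(pipe.two_mode_.cancers), "cancers,", len(pipe.two_mode_.edges), "edges")
mm = pipe.one_mode_.max_multiplicity
print("gene maximum multiplicity range:", min(mm.values()), "-", max(mm.values()))
print(pipe.assignment_.summary)
print(pipe.measure_table_.to_string(index=False))
```

prints

```
two-mode: 220 genes x 10 cancers, 300 edges
gene maximum multiplicity range: 1 - 5
         size  mean_max_multiplicity  n_causal
cluster
1          20                   4.05        20
2          25                   1.00         0
...
10         14                   1.00         0
                measure dimension  n_clusters  auc
kk_plus_multiplicity_3d        3D          10  1.0
    max_multiplicity_1d        1D           3  1.0
                  kk_2d        2D           9  1.0
       mutation_rate_1d        1D           5  1.0
```

Cluster 1 collects exactly the 20 planted drivers: their maximum
multiplicities (2–5 shared cancers) separate them from the passengers, whose
links never exceed multiplicity 1, so the cluster-score ROC against the truth
labels reaches AUC 1.0.  On real catalogs the separation is partial rather
than perfect, and the mutation-rate measure falls behind the
multiplicity-based ones.

The same pipeline runs from the shell:

```sh
multinet simulate --out sim --seed 7
multinet catalog --in sim/records.tsv --n-per-type 400 --seed 0 --out cat
multinet network --catalog cat --out net
multinet project --catalog cat --mode gene --out proj
multinet run --config config.yaml --out results/run1   # full pipeline + manifest
```

## Layout

```
src/multinet/
  catalog.py        parsing, cancer-type derivation, cohort equalization
  bipartite.py      chi-square-filtered two-mode network
  multiplicity.py   one-mode projection, m-slice, normalized link weights
  layout.py         Kamada-Kawai solver, 3D embedding
  clustering.py     Ward tree, cuts, summaries, Newick export
  evaluation.py     cluster scores, ROC, KS / Kruskal-Wallis / rank tests
  fixtures.py       synthetic catalogs with planted drivers; toy network
  pipeline.py       estimator + artifact-writing pipeline with manifest
  cli.py            `multinet` command group
docs/methods.md     model assumptions, parameter choices, limitations
```
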