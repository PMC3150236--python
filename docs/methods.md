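# Methods

## Data model and assumptions

The unit of observation is a tumor sample assayed for a gene.  All mutation
classes (substitutions, insertions, deletions) collapse to one gene-level
boolean per (sample, gene): position-level structure is deliberately ignored
to keep the representation dense enough for network analysis.  The catalog is
**closed-world**: a mutation exists iff a record asserts it, so every retained
sample counts in every gene's denominator and genes never observed mutant are
simply absent.  This overstates certainty for sparsely assayed genes — a
known property of literature-curated catalogs that the package does not try
to model.

Cancer-type labels are derived, not taken verbatim: epithelial and
soft-tissue tumors are labelled `site|histology`; haematopoietic/lymphoid
tumors and CNS gliomas are labelled by histological subtype, where the
clinically meaningful resolution lives.  The rule set is a small ordered list
(`catalog.DEFAULT_RULES`) and is fully overridable.

Cohorts are equalized (default n = 4000 per type for real catalogs; the
synthetic default is 500) by seeded sampling without replacement over
lexicographically sorted sample IDs, so the draw is independent of input row
order.  Types below the cohort size are dropped and logged.  Unequal cohorts
would otherwise let large cohorts dominate every downstream distance.

## Two-mode network

Edge inclusion asks whether gene *g* is mutated in cancer *i* "better than
chance".  Chance is operationalized as the gene's **pooled rate** r_g across
all retained types; the test is the 1-df chi-square goodness of fit over the
two cells {mutant, non-mutant} with expected counts (n·r_g, n·(1−r_g)), kept
only when observed > expected (one-sided: depletion is not an association)
and p < α, default 0.05 with no multiple-testing correction; a Bonferroni
switch exists but is off because the raw-α filter is part of the method's
definition.  Genes with pooled rate 0 or 1 have a degenerate baseline and are
skipped with a log line.  Nodes with no surviving edge are dropped.

## Multiplicity

One-mode link multiplicity is the shared-neighbor count |C′_ij| of the
bipartite graph; a node's maximum multiplicity (*m*-slice value) is its
largest incident multiplicity, with 0 for isolated nodes (on catalogs where
every network gene shares at least one cancer the observed minimum is 1; 0 is
the consistent extension).  Projection enumerates pairs per opposite-mode
node, so cost is O(Σ deg²) rather than O(|V|²).

Normalized cancer link weights: each endpoint contributes the inverse of its
mutated-gene count ‖i‖, combined by default as

    weight(i, j) = |C′_ij| · (1/‖i‖ + 1/‖j‖) / 2.

The mean rule reproduces the published endpoint contributions (1/10, 1/299)
and degrades to the unnormalized weight when ‖i‖ = ‖j‖ = 1; `sum` and `min`
rules are selectable because the combination rule is genuinely
underdetermined.

## Layout

The 2D embedding minimizes the classic spring energy with rest lengths
l_ij = L0·d_ij/max(d) and stiffness k_ij = K/d_ij², where d is the weighted
shortest-path distance over link dissimilarities δ = 1/multiplicity (the
`unit` transform, δ = 1, is available; with normalized cancer weights,
δ = 1/weight).  The inverse transform is the natural reading of multiplicity
as similarity: high-multiplicity pairs rest close.

The solver is the two-phase scheme: pick the node with the largest gradient
norm, relax it by damped 2D Newton-Raphson (falling back to steepest descent
when the local Hessian is not positive definite), with step halving so every
accepted move strictly decreases the energy — hence a non-increasing energy
trace, asserted in tests.  Energy and gradients are updated incrementally in
O(n) per move, with a periodic full recomputation to cap floating-point
drift.  Initialization is a circle of radius max(l)/2 with seeded angular
jitter; node order is canonicalized by sorting, so results are independent of
input order.  Stopping: per-node gradient norm below `gradient_tolerance`
(default 1e-4) or the outer-iteration cap (default 40·n; on large dense
networks the cap binds first, which is acceptable because downstream
clustering needs a good configuration, not a converged one).  Disconnected
components are laid out independently and packed on a grid with a margin of
one desired edge length.

The 3D embedding rescales (x, y) jointly into the unit square (aspect
preserved — relative in-plane distances are meaningful, per-axis stretching
is not) and sets z = max multiplicity / network maximum, optionally shrunk by
`z_scale` (default 1: the multiplicity axis spans the same unit as the
plane).  An all-equal multiplicity axis is degenerate and pinned to 0.5 with
a log message.

## Clustering

Ward's minimum-variance agglomeration runs on the 3D Euclidean distances via
the Lance-Williams recurrence (scipy).  Heights follow the convention in
which two singletons merge at their Euclidean distance (square root of twice
the variance increase); a squared-height convention is selectable since
published dendrogram scales vary.  Cuts are by dissimilarity threshold or by
cluster count — threshold choice itself is left to the user, since it is a
judgment call on the dendrogram.  Dendrograms export to Newick (cumulative
heights as depths) and a merge-table TSV.

## Evaluation

Cluster-level scores assign every gene its cluster's mean maximum
multiplicity divided by the top cluster mean (mean mutation rate for the
rate measure — the same construction, with rate substituted).  ROC curves
use the trapezoidal rule; with ties this equals the Mann-Whitney
U/(n⁺·n⁻) formulation, asserted against a brute-force pair count.  The four
compared measures default to 10, 3, 9 and 5 clusters respectively.

Statistical helpers: the one-tailed two-sample KS test uses
D = sup_x(F_b − F_a) for the alternative "first sample stochastically
larger" with the asymptotic tail p = exp(−2mnD²/(m+n)); Kruskal-Wallis is
tie-corrected with the chi-square reference; Spearman and Pearson report
t = r·√((n−2)/(1−r²)).  Note that for ten paired cluster observations with
r_s = 0.894 this formula gives t ≈ 5.64 — a t near 17 as sometimes quoted for
such configurations is not reproducible from the standard formula; the
package implements the standard one.  The asymptotic KS p needs moderately
large samples: the calibration test uses 400 vs 300 (KS) and 3 × 100 (KW)
standard-normal nulls over 2000 replicates, where both sit at 5.0–5.1%
rejection; at m = n = 100 the same formula is conservative (≈3.8%) because of
the lattice of attainable D values.

## Synthetic catalogs

`fixtures.generate_catalog` plants: drivers mutated at `driver_rate` (0.3) in
`driver_breadth` (5) randomly chosen cancers of `n_cancers` (10), passengers
at `passenger_rate` (0.1) in exactly one cancer, and `background_rate` (0.01)
everywhere else; per-sample flags are independent Bernoulli draws, cohorts
are 500 samples.  This emulates the *structure* the method targets — systemic
versus cancer-specific genes under equal cohorts — but not several features
of real catalogs: measurement-intensity bias (genes are assayed because they
are interesting), correlated co-occurrence/exclusivity patterns within
pathways, and heterogeneous per-cancer gene panels.  Passing tests therefore
demonstrate that the machinery recovers planted systemic structure, not that
it would rank genes identically on a curated catalog.

One consequence worth stating plainly: with these defaults the drivers'
pooled mutation rates (≈0.155) and the passengers' (≈0.019) are themselves
perfectly separated, so the mutation-rate baseline also attains AUC 1.0 on
the synthetic data and the two measures tie.  The advantage of multiplicity
over raw rate appears on data where high-rate genes can be cancer-specific —
the regime real catalogs occupy — and is not exhibited by this generator's
default regime.

`fixtures.figure1_toy` freezes a minimal witness network with the
worked-example properties (one gene pair sharing exactly one cancer, one
sharing two, every gene's maximum multiplicity 2); the exact published
topology is not recoverable from text, so any witness satisfying the stated
properties is equivalent for testing.

## Numerical and design choices

- Chi-square p values come from the χ²(1) upper tail; the statistic is exact
  algebra, so the hand-computable examples match to rounding.
- Shortest paths: Dijkstra on a sparse graph; cross-component distances are
  ∞ and are never fed to the spring solver.
- Ward tie-breaks follow scipy's deterministic nearest-neighbor-chain order;
  cut labels are renumbered by first appearance in leaf order so outputs are
  stable across runs.
- Sampling, layout jitter and the fixture generator all consume
  `numpy.random.default_rng` seeded from explicit integer parameters; a
  pipeline rerun with the same config is byte-identical (asserted in tests).
- Problem sizes in the test suite are scaled to the structure being checked
  (e.g. 6-cancer catalogs for layout-heavy paths, n ≤ 6 point sets for the
  exhaustive Ward oracle); the planted-driver recovery checks run the full
  default generator over 20 seeds.

## Known limitations

- The expected-count model behind the edge filter (pooled-rate baseline) is
  one reading of "better than chance"; covariate-adjusted or exact tests are
  out of scope.
- The layout cap means very large networks stop on iteration budget rather
  than gradient tolerance.
- Cluster-count defaults (10/3/9/5) are study-specific conventions, not
  data-adaptive choices.
- The closed-world assumption ignores which genes were actually assayed per
  sample; tested-gene denominators are intentionally not modeled.
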