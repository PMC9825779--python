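# Methods

## The quantity being computed

A linked taxa–function dataset consists of a taxon abundance matrix
A (taxa × samples) and a copy-number matrix G (taxa × functions). The
contributor set of function f is C(f) = { taxon t : G[t, f] > 0 }; copy
number enters only through this threshold, so single-copy and multi-copy
encoders are interchangeable. Contributional alpha diversity of (f, s) is
an alpha metric evaluated on the restricted vector A[C(f), s];
contributional beta diversity of (f, s, t) is a dissimilarity between
A[C(f), s] and A[C(f), t]. The restricted vectors are used **raw** — they
are not renormalised against whole-community totals. Proportion-based
metrics normalise internally, so for them this choice is equivalent to
renormalising; for count-based metrics (Fisher's α, Margalef, Menhinick,
McIntosh) it means totals are the summed abundances of the contributors,
which is the natural reading of "diversity of the taxa that encode the
function". This convention is documented rather than configurable.

## Alpha metrics

All fifteen built-ins are listed with formulas in
`contribdiv/alpha_metrics.py`. Conventions that matter:

- **Log base.** Shannon-family metrics use base 2 by default (bits),
  configurable via `base=`. Pielou's J is base-free (ratio); Heip's
  evenness uses the natural log internally, as its definition requires.
- **Missing values.** A zero-sum vector, an evenness at richness ≤ 1
  (division by log S = 0 or S − 1 = 0), and a Fisher's α with no finite
  root all return NaN, never raise. Absence of a defined value is treated
  as information for downstream filtering.
- **Counts.** Metrics flagged `requires_counts` depend on the total N, not
  only on proportions. Given non-integer input they proceed on the totals
  as given; nothing is rounded silently.
- **Fisher's α** solves S = α·ln(1 + N/α) by Newton iteration from
  α₀ = S, tolerance 1e−8 on the back-substituted residual, at most 100
  iterations. Since sup_α α·ln(1 + N/α) = N, the equation has no finite
  root when S ≥ N; that case (and any non-convergence) warns and returns
  NaN.
- **Faith's PD** is the total branch length of the union of root-to-tip
  paths of present tips (strict > 0 presence), 0 for an empty vector.

User metrics are added through `register_metric` (name collisions error
unless `override=True`); the built-in names are the CLI vocabulary.

## Phylogenetic machinery

Trees are read as written and treated as rooted; no midpoint re-rooting is
performed, and because UniFrac depends on the root, users who want a
different root must re-root upstream. Every non-root edge must carry a
non-negative length (zero-length edges are allowed and contribute
nothing); multifurcations are fine.

For speed, both UniFrac variants and the workflow-level Faith's PD run on
a *branch table*: one pass over the tree records, for every branch on a
root path of a listed tip, its length ℓ_b and a boolean mask of descendant
tips. Then

- unweighted UniFrac = Σ ℓ_b·[present in exactly one sample] /
  Σ ℓ_b·[present in either],
- weighted UniFrac (raw) = Σ ℓ_b·|p_b − q_b| with p_b the fraction of the
  sample's total abundance descending b; the normalised variant (default,
  bounded to [0, 1]) divides by Σ ℓ_b·(p_b + q_b).

Computing on full-tree masks is mathematically identical to pruning the
tree to the present tips first; the test suite checks this equivalence on
random trees, along with brute-force branch-enumeration oracles and the
star-tree reductions (on a unit-branch star tree, unweighted UniFrac
collapses to binary Jaccard and normalised weighted UniFrac to
Bray–Curtis of relative abundances).

## Beta metrics and missing values

Jensen–Shannon divergence uses natural logs (maximum ln 2) and reports the
divergence, not its square root; a `base` argument rescales. Hellinger is
the Euclidean distance between square-rooted relative-abundance vectors;
Whittaker's index of association is half the Manhattan distance between
relative-abundance vectors. Presence thresholds are strict (> 0).

When exactly one vector of a pair is all-zero the formula is followed
(Bray–Curtis gives 1, Euclidean gives the norm); when both are all-zero
the value is undefined and reported NaN, symmetrically, including on the
diagonal. A function with no contributors therefore produces an all-NaN
matrix; an all-NaN alpha row appears for the same reason (0 instead under
`zero_fill`). These conventions are declared package behaviour — there is
no community consensus for the degenerate cases.

## Parallelism

Work is chunked by function and gathered in input-function order, so
output is bit-identical for any worker count (there is no randomness in
any core path). Threads are used rather than processes: the hot loops are
NumPy reductions that release the GIL, and thread workers avoid pickling
overhead for closures over large tables. A worker failure is re-raised
tagged with the offending function id.

## Synthetic data generator

`fixtures.generate_fixture` emulates the *shape* of MAG datasets, not
their ecology: lognormal (default, right-skewed) or uniform abundances
with a fixed 20% per-cell dropout so absence paths are exercised (columns
are kept non-empty deterministically); Bernoulli copy-number presence with
probability 1 − sparsity (default sparsity 0.3, a mid-range gene-repertoire
sparsity) and copy numbers 1–3; a random bifurcating tree grown by
splitting a uniformly chosen tip edge, with exponential(1) branch lengths.
A single integer seed drives one `numpy` Generator with a documented draw
order (abundances, dropout, copy-number presence, copy-number magnitudes,
topology, branch lengths), so fixtures are reproducible across versions.
No compositional covariance, phylogenetic signal in gene content, or
sequencing noise is simulated — passing tests demonstrate correctness of
the computations, not robustness to real-data artefacts.

The fixed worked example (`generate_toy_worked_example`) uses the tree
`((A:1,B:1):1,C:2);` with samples s1 = {A: 5, C: 2}, s2 = {B: 3, C: 1} and
functions f1 = {A, B}, f2 = {A, B, C}, chosen so the closed-form values
(Faith's PD of {A, B} = 3; between-sample unweighted UniFrac under f2 =
2/5) are checkable by hand.

## Problem sizes and numerics

The default test suite and the acceptance script run on small synthetic
datasets (up to 40 taxa × 12 samples × 200 functions), which is where the
exhaustive hand-restriction and brute-force oracle comparisons are
feasible; the implementation itself is vectorised and scales linearly in
the number of functions. Floating-point comparisons in tests use 1e−12
absolute tolerance for closed-form metrics and 1e−9 for tree metrics
(branch sums accumulate in different orders in the oracle). Table readers
parse floats in round-trip precision mode so write→read is exact.

## Known limitations

- No rarefaction, coverage estimators or Hill-number unification.
- BIOM/HDF5 input is not parsed; convert to TSV upstream. Stratified
  "function|taxon" row formats can be reshaped to the long dialect with a
  few lines of pandas (split on `|`, melt, rename).
- Ordination and visualisation of the per-function distance matrices are
  out of scope; matrices are written as plain TSV for downstream tools.
- UniFrac values are only comparable across functions when computed on the
  same rooted tree.
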