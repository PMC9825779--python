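# contribdiv

Contributional diversity for linked taxa–function microbiome data.

Metagenome-assembled genomes (MAGs) and tools that stratify functional
profiles by taxon produce *contributional data*: for every function (a KEGG
ortholog, a MetaCyc pathway, a gene family, …) we know which taxa encode it
and how abundant those taxa are in each sample. `contribdiv` computes, for
every function separately:

- **contributional alpha diversity** — the within-sample diversity of the
  taxa that encode the function, and
- **contributional beta diversity** — the between-sample divergence of
  those same contributing taxa.

A taxon *contributes* a function when its copy number for that function is
strictly positive; copy-number magnitude is deliberately ignored (single-
and multi-copy contributors are equivalent). For a function *f* with
contributor set C(f) and abundance vector x_s over taxa in sample *s*, the
alpha value at (f, s) is α(x_s restricted to C(f)) and the beta value at
(f, s, t) is d(x_s|C(f), x_t|C(f)).

Fifteen alpha metrics are built in — richness, Shannon H′ (−Σ pᵢ log₂ pᵢ),
Gini–Simpson (1 − Σ pᵢ²), inverse Simpson, Simpson/Pielou/Heip/McIntosh
evenness, Berger–Parker and McIntosh dominance, ENS-PIE, Fisher's α,
Margalef and Menhinick richness, and Faith's phylogenetic diversity (the
branch length spanning the present tips' root paths of a rooted tree).
Beta metrics include Bray–Curtis, binary Jaccard, Jensen–Shannon
divergence, weighted and unweighted fast UniFrac (computed over a
precomputed per-branch descendant table), and the common geometric
distances (euclidean, manhattan, canberra, chebyshev, hellinger,
whittaker). Both registries accept user-defined metrics.

## Input formats

- wide **abundance** TSV: taxa × samples, first column taxon labels;
- wide **copy-number** TSV: taxa × functions;
- long **contributional** TSV with columns `sample`, `func`, `taxon`,
  `taxon_abun` (+ optional `genome_function_count`); the `picrust2`
  dialect (`function` column name, extra columns ignored) is also read.
  `contribdiv convert` translates between the formats.

Gzip-compressed tables are read transparently. Phylogenies are rooted
Newick trees whose tips cover the taxa.

## Worked example

Three taxa on the tree `((A:1,B:1):1,C:2);`. Sample s1 contains A (5) and
C (2); sample s2 contains B (3) and C (1). Function f1 is encoded by A and
B; f2 by all three taxa.

```python
from contribdiv import generate_toy_worked_example, alpha_div_contrib, beta_div_contrib

toy = generate_toy_worked_example()
alpha = alpha_div_contrib(toy.abund, toy.cn,
                          metrics=["richness", "faiths_pd"], tree=toy.tree)
print(alpha["faiths_pd"])
#      s1   s2
# f1  2.0  2.0
# f2  4.0  4.0

beta = beta_div_contrib(toy.abund, toy.cn,
                        metrics=["unweighted_unifrac"], tree=toy.tree)
print(beta["unweighted_unifrac"]["f2"].data)
#      s1   s2
# s1  0.0  0.4
# s2  0.4  0.0
```

Reading the numbers: under f1 only one contributor is present per sample
(A in s1, B in s2), so its Faith's PD is that tip's root path (1 + 1 = 2).
Under f2 the present contributors are {A, C} in s1 (branches 1 + 1 + 2 = 4)
and {B, C} in s2. Between the samples, the A and B tip branches are
unshared while the AB stem and the C branch are shared, giving unweighted
UniFrac 2/5 = 0.4. If both samples carried the same contributors the
distance would be 0; phylogenetically disjoint contributor sets give 1.

The same computations from the shell:

```sh
contribdiv fixture --n-taxa 20 --n-samples 8 --n-functions 30 --seed 1 --outdir data/
contribdiv alpha --abund data/abundance.tsv --func-table data/copy_numbers.tsv \
    --tree data/tree.nwk --metrics all --workers 4 --outdir alpha_out/
contribdiv beta  --contrib data/contrib.tsv --tree data/tree.nwk \
    --metrics bray_curtis,weighted_unifrac --outdir beta_out/
```

`alpha` writes one functions × samples TSV per metric; `beta` writes one
sample × sample matrix per function under `outdir/<metric>/`, with a
`function_id_map.tsv` recording filesystem-safe filenames. A (function,
sample) cell whose contributors are all absent is reported as NA (or 0
with `--zero-fill`); a function encoded by no taxon yields an all-NA
row/matrix, never an error. Results are bit-identical for any `--workers`
value.

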