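# sagmag

Comparative analysis of two genome-recovery strategies for one microbial
community: randomised **single-amplified genomes (SAGs)** versus
**metagenome-assembled genomes (MAGs)**, benchmarked against 16S amplicon
and shotgun read profiles.  The package provides, as a library and a
`sagmag` command-line pipeline over plain TSV/FASTA inputs:

* **Compositional differential abundance** — per-sample lineage counts are
  prevalence-filtered (> 90% of every method's samples), expanded into
  Dirichlet Monte-Carlo instances (`Dirichlet(counts + 0.5)`, n = 1000 by
  default), centred-log-ratio transformed, and compared across methods
  with the Games-Howell post-hoc test; a lineage is called at
  `|expected difference| > 2` CLR units and `expected p < 1e-3`.
* **Statistical primitives** — a vectorised studentized-range tail
  probability (quadrature of the classical double integral; at k = 2 it
  reduces exactly to Welch's t-test), the Games-Howell test with
  Welch-Satterthwaite degrees of freedom

      t = (x̄_i − x̄_j) / sqrt(s²_i/n_i + s²_j/n_j),
      p = P(Q_{k,df} ≥ |t|·√2),

  and an exact paired Wilcoxon signed-rank test (full sign enumeration up
  to 25 nonzero differences, mid-ranks for ties).
* **Greedy identity clustering** — global affine-gap alignment identity
  (terminal gaps penalised but excluded from the identity denominator)
  driving CD-HIT/MMseqs2-style greedy clustering of genes and 95%-ANI
  dereplication of genomes; rank-wise shared/unique taxon counts and Venn
  counts of clusters by collection.
* **Pangenome accumulation** — permutation rarefaction curves (1000
  orderings) with their hypergeometric closed form
  `E[S(g)] = Σ_c [1 − C(N−n_c, g)/C(N, g)]` as an exact cross-check.
* **KEGG-module gene content** — module presence at ≥ 75% KO
  completeness, retention at ≥ 5% prevalence or reference-genome support,
  merging of ≥ 65%-overlapping modules into categories, gene counts
  standardised by isolate medians, and per-category Games-Howell calls at
  p < 1e-3.
* **Chimera auditing** — default clade-separation-score calls
  (CSS > 0.45), a stringent consensus caller (CSS ≥ 0.85 and RRS ≥ 0.5 at
  a rank above genus, plus an independent contamination estimate ≥ 10%),
  estimator-incongruence regression, and 16S-vs-genome taxonomy conflict
  counting.
* **Fragment recruitment** — per-sample recruited-read fractions over an
  identity-threshold grid, compared between reference sets with the exact
  paired signed-rank test.
* **Synthetic data with ground truth** — generators for every input the
  pipeline consumes (community counts, genome metadata, gene catalogs with
  core/flexible structure, contamination reports with planted chimeras,
  16S assignments with planted conflicts, recruitment summaries), all
  byte-reproducible under a seed.

See `docs/methods.md` for the models, parameter defaults and numerical
choices.

## Worked example

Simulate a community observed by four methods, with an 8-fold planted
abundance shift of one lineage in the MAG method and 5% planted chimeric
assemblies, then run two stages:

```bash
sagmag simulate --outdir demo --seed 7 --n-lineages 20 --n-samples 10 \
    --n-sag 60 --n-mag 60 --n-isolate 8 --n-core 40 --n-flexible 80 \
    --chimera-fraction 0.05 --planted-method MAG --planted-fold 8
sagmag composition --counts demo/counts.tsv --outdir demo --n-mc 100 --seed 3
sagmag chimera --gunc demo/gunc.tsv --mdm demo/mdm.tsv \
    --genomes demo/genomes.tsv --outdir demo
```

The composition stage logs

```
INFO sagmag: composition: 20 lineages pass the prevalence filter
INFO sagmag: composition: 3 significant lineage/pair calls
```

and `demo/diffabund.tsv` contains exactly the planted lineage, flagged in
the three method pairs that involve MAG, with MAG-positive differences —
for example:

```
order_004  SAG_vs_MAG       -2.295  3.4e-10  True
order_004  MAG_vs_AMPLICON   2.308  1.8e-10  True
order_004  MAG_vs_SHOTGUN    2.288  2.5e-10  True
```

The estimated difference is in CLR (natural-log-ratio) units: the planted
lineage is about `e^2.3 ≈ 10`-fold enriched in MAG profiles relative to
the geometric mean shift of the other lineages, and the sign identifies
the enriched method.  The chimera stage logs

```
INFO sagmag: chimera: 22 default calls, 6 consensus calls
```

— the 6 consensus calls are exactly the 6 planted chimeras recorded in
`demo/truth.json` (0.05 × 128 genomes), while the default CSS > 0.45 rule
also fires on the planted near-miss genomes (high CSS at genus rank, or
poor reference representation), illustrating why the stringent consensus
is the trustworthy call.

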