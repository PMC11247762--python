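# Methods

`sagmag` re-implements, as a tested pipeline over plain tab-separated
tables, the comparative computations used to judge how faithfully two
genome-recovery strategies — randomised single-amplified genomes (SAGs)
and metagenome-assembled genomes (MAGs) — represent one marine
prokaryoplankton community.  This note records the models, the parameters
that matter, the numerical choices, and what the synthetic-data study does
and does not demonstrate.

## Compositional differential abundance

Lineage count tables are compositional: only relative information is
meaningful.  The pipeline follows the ALDEx2-style recipe:

1. **Prevalence filter.**  A lineage is analysed only if it is observed
   (count > 0) in strictly more than 90% of the samples of *every*
   observation method (SAG, MAG, amplicon, shotgun).  The comparison is
   strict: 9 of 10 samples does not pass at the 0.9 default.
2. **Dirichlet Monte Carlo.**  For each sample, `n_mc` probability vectors
   are drawn from `Dirichlet(counts + 0.5)`.  The prior mass of 0.5 per
   cell is the convention of the cited procedure; it is exposed as a
   parameter.  Zero counts are handled only through this prior — no other
   pseudo-proportion is injected anywhere.
3. **CLR transform.**  Each instance is centred-log-ratio transformed:
   `clr(x)_i = ln x_i − mean_j ln x_j`.  CLR differences are therefore in
   natural-log units and invariant to depth rescaling.
4. **Games-Howell across methods.**  Per lineage and Monte-Carlo index, a
   Games-Howell post-hoc test is run across the four methods on the
   per-sample CLR values (unequal n and unequal variances are handled by
   construction).
5. **Aggregation and dual cutoff.**  The per-instance estimated
   differences and p-values are aggregated by arithmetic mean (median
   available); a (lineage, method pair) is flagged when
   `|expected difference| > 2` CLR units **and** `expected p < 1e-3`,
   both strict.

Per-instance testing followed by averaging (rather than averaging CLR
values and testing once) was chosen because it propagates the count
uncertainty into the reported p-value; both routes are exposed through the
`n_mc` and aggregation parameters.

### Why the planted effect is an 8-fold *proportion* shift

A pure multiplicative bias `b` on one of `D` lineages shifts that
lineage's CLR by `ln(b)·(1 − 1/D)` — at `b = 8, D = 20` that is 1.976,
which sits *below* the dual cutoff of 2 by construction, for any
abundance.  The generator therefore plants effects as "the lineage's final
proportion is `b`-fold its base proportion, all other lineages
renormalised", which adds the renormalisation term
`−ln c · (1 − 1/D), c < 1` and clears the cutoff for lineages that are
not vanishingly rare.  The planted lineage is chosen as the one whose true
proportion is nearest 4% so the effect size is controlled across random
communities.

## Games-Howell test and the studentized range

For groups *i, j* with sample means `x̄`, n−1 variances `s²` and sizes
`n`:

    d  = x̄_i − x̄_j
    SE = sqrt(s²_i/n_i + s²_j/n_j)
    t  = d / SE
    df = (s²_i/n_i + s²_j/n_j)² / [ (s²_i/n_i)²/(n_i−1) + (s²_j/n_j)²/(n_j−1) ]
    p  = P( Q_{k,df} ≥ |t|·√2 )

with `Q_{k,df}` the studentized range of `k` groups and the confidence
interval half-width `q_{1−α,k,df}·SE/√2`.  At `k = 2` the procedure
reduces exactly to Welch's t-test — a property the test suite checks to
1e-9 against an independent implementation.

The studentized-range survival function has no closed form; it is
computed by quadrature of the standard double integral (chi-scaled outer
integral, normal-range inner integral).  Numerical choices:

* Inner integral on `z ∈ [−9, 9]` (truncation error below 1e-18) with
  composite Gauss-Legendre panels.
* Outer integral on a chi-quantile-bounded interval (mass 1e-16 truncated
  at each end) with panels geometrically graded toward the lower endpoint,
  which controls the `s^{df−1}` power behaviour of the chi density at
  `df < 2` (Welch df can approach 1).
* Default grid: absolute error near 1e-10 against scipy's reference
  implementation; a coarser `fast=True` grid (~1e-6) is used for the
  Monte-Carlo bulk path, where millions of tail evaluations feed a mean
  p-value compared against a 1e-3 cutoff — 1e-6 noise is immaterial there.
* The inverse (`isf`, used only for confidence intervals) is obtained by
  bracketed root finding on the accurate grid.

## Exact paired Wilcoxon signed-rank test

Zero differences are discarded before ranking (classic reduction); tied
absolute differences receive mid-ranks.  With `n ≤ 25` nonzero
differences the two-sided p-value is exact: the null distribution of the
positive-rank sum is built by dynamic programming over the doubled
(hence integral) mid-ranks, and `p = min(1, 2·min(P(W ≤ w), P(W ≥ w)))`.
Beyond 25 the normal approximation with tie and continuity corrections is
used.  The all-positive pattern over 8 pairs gives exactly
`2/2⁸ = 0.0078125`.

## Sequence identity and greedy clustering

Pairwise identity is computed from a global Gotoh alignment with affine
gaps (defaults: match +2, mismatch −3, gap open −5, gap extend −2; the
parameters must be multiples of 0.25 so tie handling is exact in integer
arithmetic).  Terminal gap runs are charged the same affine penalty but
excluded from the identity bookkeeping: the *core* of the alignment runs
from the first to the last match/mismatch column, identity is
matches/core-columns, and each sequence's coverage is the fraction of its
residues inside the core (giving CD-HIT's shorter-sequence-coverage
semantics).  Among co-optimal alignments the most matches, then the
fewest core columns, win — a deterministic rule replayed verbatim by the
test suite's exhaustive path-enumeration oracle.  Wildcards (N/X) occupy
columns and are scored as mismatches, never as matches.

Greedy clustering processes sequences by decreasing length (ties by id)
and joins each to the *best* representative (highest identity) meeting
both the identity and coverage thresholds, not the first acceptable one —
a deliberate, order-robust divergence from the incremental tools it
stands in for; ties go to the earliest-created cluster.  ANI
dereplication applies the same greedy rule to a symmetric percent-identity
matrix, ranking genomes by completeness (the quality signal available to
the dereplication step), joining at ≥ 95% ANI to the first qualifying
representative.

## Pangenome accumulation

Richness counts distinct clusters, never genes.  The permutation curve
averages cumulative distinct-cluster counts over random genome orderings
(1000 by default, n−1 standard deviation).  Its analytic twin is

    E[S(g)] = Σ_c [ 1 − C(N−n_c, g) / C(N, g) ]

evaluated through log-gamma (relative error well below 1e-10); the two
agree within Monte-Carlo error at every depth, which the suite asserts.

## KEGG-module gene-content comparison

Six steps: (1) module completeness = fraction of the module's KOs present
in the genome; (2) presence at completeness ≥ 0.75 (inclusive, "at
least"); (3) retention of modules present in ≥ 1 fully annotated
reference genome *or* in ≥ 5% (inclusive) of the pooled SAG+MAG genomes —
pooled rather than per-collection, with the per-collection reading left to
the caller via the presence matrix; (4) merging of modules whose KO
overlap `|A∩B|/min(|A|,|B|)` is ≥ 0.65 into connected-component
categories (the `min` denominator makes a nested submodule count as full
overlap, which is exactly the double-counting the merge exists to
prevent; Jaccard is exposed as an alternative), represented by the
largest member; (5) per-genome gene counts over each category's KO union
(a gene counts once even if several member modules claim its KO), divided
by the median count in cultured isolate genomes — an even number of
isolates takes the midpoint, a zero isolate median falls back to the
all-genome median, and a category with zero fallback median is dropped
with a logged notice; (6) Games-Howell (k = 2) per category with
significance at p < 1e-3, the sign of the difference reporting which
collection is enriched (SAG-positive).

Note that re-merging merged categories may coarsen the partition further
(unions can newly overlap); the merge is idempotent only when the
resulting KO unions stay below the threshold pairwise.

## Chimera calling

The default call flags a genome when the clade separation score exceeds
0.45 (strict, following the reporting convention) at any rank; an
optional restricted view considers only ranks with reference
representation above 0.5.  The stringent consensus call requires, at a
single rank strictly above genus (family, order, class, phylum, domain):
CSS ≥ 0.85 and RRS ≥ 0.5, *and* an MDMcleaner-style contamination
fraction ≥ 0.10.  Evaluating the CSS/RRS conditions jointly at one
qualifying rank is the coherent reading of "contamination detected above
the genus level"; the evidence rank reported is the qualifying rank with
the highest CSS.  Consensus calls are a subset of default calls by
construction (0.85 ≥ 0.45), and lowering any threshold can only add
calls — both properties are tested.  For the estimator-incongruence plot
the GUNC contamination fraction is taken at the genome's maximum-CSS rank
(the rank GUNC itself emphasises), and MDM is regressed on GUNC by
ordinary least squares.

## 16S conflict audit

A genome mismatches at a rank only when both the genome taxonomy and a
16S assignment are non-empty there and differ — an empty label is
"unassigned" and never conflicts, including with another empty label.
Multi-copy conflicts are two 16S copies of one genome assigned and
mutually different at a rank.  Per-collection recovery is the fraction of
genomes with at least one 16S sequence.

## Fragment recruitment

Per sample and reference set, the recruited fraction is the share of
reads with best-hit identity at or above the threshold and alignment
length ≥ 100 bp (the two length-type conditions of the upstream mapper
collapse to one filter because the summary carries a single alignment
length).  One best alignment per read per reference set is assumed.  The
default identity grid is {1.00, 0.98, 0.95, 0.90, 0.85, 0.80}; SAG and
MAG fractions are compared per threshold with the exact paired signed-rank
test across samples.

## Synthetic data: what it emulates, and what it does not

All pipeline inputs are generated with known ground truth; every
generator is a pure function of its parameters and a seed, so one seed
reproduces the tables byte for byte (the run manifests' timestamps are the
only non-reproducible output).  Default study conditions:

* **Community**: 40 lineages from a symmetric Dirichlet (concentration 2,
  a moderately uneven community), 20 samples per method, multinomial
  depths uniform in [5·10⁴, 2·10⁵].  The composition-control experiments
  use 20 lineages and 10 samples per method with n_mc = 200, sizes at
  which the null and planted-effect behaviour is measured over 100
  replicates.
* **Collections**: 400 SAGs drawn proportional to true abundance, 400
  MAGs drawn proportional to abundance^0.3 (tempering enriches rare
  lineages, emulating assembly/binning bias), 15 isolates; completeness
  normal around 69% (SAG) / 71% (MAG), clipped to [50, 99].
* **Gene catalog**: 300 core + 1200 flexible ancestral families of 300 bp;
  per-genome dropout 0.1, raised to 0.6 for flexible genes in MAGs;
  per-copy substitution rate 0.02; one KO per family, modules of 8 core
  KOs with every third module overlapping its predecessor (exercising the
  merge); one module's genes additionally dropped from MAGs at 0.6 — the
  planted gene-content effect.  The emitted FASTA is a toy window (first
  40 families × first 8 genomes) sized for alignment-based clustering in
  seconds; genome-wide memberships travel in the annotation table.
* **Quality reports**: 4% planted chimeras satisfying every consensus
  condition at one above-genus rank (CSS 0.90–1.00, RRS 0.60–0.90, MDM
  0.12–0.45); every clean genome is constructed to fail at least one
  condition, including deliberate near-misses (genus-rank CSS spikes,
  high-CSS/low-RRS ranks, strong GUNC signal with MDM < 5%) so default
  and consensus calls genuinely differ.  2% planted 16S conflicts swap
  one copy's domain or phylum.
* **Recruitment**: 24 samples × 2000 reads; each reference set covers a
  random lineage subset, thinned so the expected recruited fraction equals
  the coverage target exactly — without thinning, the random overshoot of
  the covered mass would plant a spurious systematic SAG/MAG difference
  that a paired test across 24 samples reliably detects.  Identity is
  1 − |N(0, 0.03)| with a 0.3 point mass at exact identity; alignment
  lengths are normal (150 ± 30) so a realistic tail falls below the
  100 bp filter.

The generators reproduce the *statistical structure* the analysis assumes
— shared community, method biases, core/flexible gene architecture,
threshold-straddling contamination scores — not real sequence evolution:
taxa are synthetic labels, gene families are unrelated random sequences
mutated independently, 16S copies carry no sequence, and read recruitment
has no alignment behind it.  Passing tests therefore demonstrate that the
implementations compute their definitions correctly and recover planted
effects at the stated sizes; they say nothing about upstream assembly,
binning, annotation or classification quality on real data.

## Problem sizes in the verification suite

The acceptance checks run the statistics at the sizes named above: 500
random datasets for the Welch equivalence, a 10⁶-draw Monte-Carlo oracle
for the studentized range, 100 replicates each for the null-composition
control, the planted lineage shift and the planted module depletion, 200
random instances for the greedy-clustering replay, exhaustive alignment
enumeration at lengths ≤ 8, a 20 × 50 incidence fixture at 1000
permutations, a 500-genome chimera fixture with 20 planted chimeras, and
two full CLI workflow runs compared byte for byte.

## Known limitations

* The alignment kernel is quadratic with no k-mer prefilter; it is meant
  for desk-scale catalogs (≤ a few thousand short genes), not for
  clustering millions of sequences.
* Module presence uses the KO-fraction rule only; boolean reaction-path
  definitions (AND/OR logic) are out of scope.
* The MDM contamination fraction is treated as an abstract fraction in
  [0, 1]; whether the upstream tool reports gene or length fractions is
  not modelled.
* Games-Howell is two-sided only, and no pooled-variance post-hoc
  alternative is provided.
* The epipelagic depth cutoff (100 m) in the metadata filter is a
  configuration default, not a measured value.
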