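# Methods

## Object model and conventions

A **genome layout** is an assignment of gene labels to a fixed multiset of
loci (chromosome + half-open interval).  All coordinates are 0-based
half-open internally; BED input is taken as-is and 1-based inclusive TSV
is converted on load.  Genes whose id occurs at more than one position are
dropped entirely (no copy is kept), since an ambiguous position cannot be
permuted meaningfully.  Within a chromosome genes are ordered by start.

**Linear distance** between two genes is the absolute difference of their
interval midpoints, `floor((start+end)/2)`.  Midpoints are the only anchor
that remains well-defined for merged tandem genes, which span wide
intervals; start- or gap-based anchors would make merged genes look
artificially close to their neighbours.  Distance across chromosomes is
undefined (never a sentinel value).

**Tandem duplicate merging**: maximal runs of genes that are adjacent in
the per-chromosome order and share a gene-family id are replaced by one
gene spanning the run, with composite id `a|b|…`.  Original ids alias to
the merged gene, so group files that predate merging still resolve; two
group members collapsing onto one merged gene shrink the group
accordingly.  Merging is idempotent because composite ids belong to no
family.  Family assignment is consumed as input (e.g. from a
sequence-clustering pipeline); computing it is out of scope.

## Permutation null models

Two schemes randomize gene order while holding everything else fixed:

* **global** — labels are dealt uniformly at random to all loci.  The
  locus multiset and the number of genes per chromosome are invariant, so
  chromosome sizes and gene density are not part of the null hypothesis.
* **within-chromosome** — labels are shuffled independently inside each
  chromosome.  Additionally every gene's chromosome is invariant, which
  holds each group's chromosome composition (and hence its number of
  intra- and inter-chromosomal pairs) fixed.  This scheme underlies the
  intra-chromosomal distance tests and the inter-chromosomal-only spatial
  tests, where dispersal effects must not leak in.

Group composition is never altered.  The empirical p-value of an observed
statistic v₀ against n replicates is (k+1)/(n+1) with ties counted toward
k; the +1 correction makes the p-value super-uniform under the null at any
n, with floor 1/(n+1).  Direction is explicit per statistic: `le` for
mean-distance and mean-chromosome-count statistics (concentration = small
values), `ge` for enrichment counts.  Replicates are drawn independently
with replacement from the permutation space by a single PCG64 generator
seeded per test; no attempt is made to enumerate distinct permutations,
and exact agreement with exhaustive enumeration is verified on tiny
genomes in the test suite.  A replicate on which a statistic is undefined
(e.g. no eligible pair survives) counts as not extreme — the conservative
direction; an undefined statistic on the *real* layout is an error.

## Registered statistics

Six scalar statistics are registered for the pipeline and CLI:

| name | definition | scheme | direction |
| --- | --- | --- | --- |
| `mean_chrom_count` | mean over groups of #chromosomes containing members | global | le |
| `single_chrom_enrichment` | #groups entirely on one chromosome | global | ge |
| `intra_linear_group_mean` | mean over groups of mean intra-chromosomal pair distance d_i | within | le |
| `spatial_all_group_mean` | mean over groups of mean 1−r over all pairs | global | le |
| `spatial_inter_group_mean` | same, inter-chromosomal pairs only | within | le |
| `spatial_inter_pairs` | mean over all pooled inter-chromosomal pair distances | within | le |

Group means are unweighted over groups (not pair-weighted); groups with no
eligible pair are omitted from the mean rather than scored with a
sentinel.  For linear intra-chromosomal distances under the
within-chromosome scheme the omission set is invariant across replicates;
for spatial statistics it can differ (missing segments), which the
pipeline logs.

## Spatial distances

The contact map is a symmetric segment-by-segment matrix of normalized
contact scores at fixed segment size.  The distance between segments i and
j is 1 − Pearson correlation of their matrix rows, computed over columns
where both rows are defined and **excluding columns i and j themselves**,
so the inflated self/near-self entries cannot dominate the correlation.
Correlations with fewer than `min_overlap` shared defined columns
(default 10) or zero variance are undefined.  Missing entries are excluded
pairwise, never imputed as zero.  Distances lie in [0, 2]; a segment's
self-distance is 0.  Genes map to the single segment containing their
midpoint.  Two genes in one segment are at distance 0.  Pearson (not
rank) correlation follows standard contact-map practice.

## The distribution tail test

Given per-group (or per-pair) values, concentration shows up as an excess
of *small* values.  Thresholds 0 = t₀ < t₁ < … < t_k are the k
equal-occupancy quantiles of the **real** values (linear interpolation,
type-7; k = 20 by default, so the real cumulative curve is a straight
line by construction).  Integer-valued chromosome counts use natural bins
{1}, {2}, … instead, since quantile bins degenerate under such heavy
ties.  Each replicate's values are binned by the same thresholds;
replicate values above t_k fall into an overflow bin excluded from every
cumulative count, which can only lower replicate prefix counts — the
conservative direction.  For each prefix j the cumulative count
F_j = f₁+…+f_j gets an empirical p-value p_j (direction ge), and the
result is the minimal j with j·p_j ≤ α, reported with corrected p-value
j·p_j capped at 1.  The full p_j vector is retained so multi-bin
significance ranges are reportable.  An optional lexicographic order on
whole prefix vectors (replicate extreme iff (F₁, F₂, …) ≥ the real vector
lexicographically, equality inclusive) is available as an alternative
extremeness definition for tie-heavy data.

The j-search uses the fixed nominal α and thresholds computed once from
the real values (never recomputed per replicate); both choices are this
package's conventions, stated here because reasonable alternatives exist.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not any particular karyotype.  Defaults define the reference study
condition used by the test suite: 2 chromosomes × 100 genes, gene bodies
~ Gamma(shape 2, mean 10 kb), intergenic gaps ~ Exponential(mean 40 kb)
(so chromosomes of roughly 5 Mb whose lengths emerge from the draws,
mimicking variable gene density), 50 groups with sizes uniform on 2–8,
250 kb contact-map segments.  These sizes keep a full permutation test in
tens of milliseconds, so calibration and power can be measured over
hundreds of full runs inside the test suite.

Planted signal is parameterized by mixture probabilities so power curves
are comparable across configurations:

* `chrom_concentrated`: each member is drawn from the group's anchor
  chromosome with probability ρ, uniformly otherwise;
* `linear_clustered`: with probability ρ a member is drawn from the genes
  within ± window/2 of an anchor gene (window = 5% of the chromosome by
  default), so any two clustered members are at most one window apart.
  At ρ = 1 an undersized candidate pool is an error rather than a silent
  relaxation;
* contact maps: intra-chromosomal entries decay as (1+d)^(−α) in segment
  offset, inter-chromosomal entries sit at a small constant, and planted
  inter-chromosomal segment pairs are blended toward a shared anchor
  profile with weight σ (connected components of the planted-pair graph
  share one anchor, so overlapping pairs stay consistent).  At σ = 1 and
  zero noise, planted profiles coincide and their distance is exactly 0;
  at σ = 0 planted pairs are indistinguishable from background.
  Symmetric Gaussian noise (sd 0.05 by default) is added last.

`choose_planted_pairs` selects the inter-chromosomal segment pairs
hosting the most group gene pairs, coupling the planted 3D signal to the
collection — the ground truth the individual-pair spatial test is meant
to recover.  Everything is a pure function of (config, seed); distinct
generators draw from independent sub-streams of the seed.

What passing tests on these synthetics do **not** show: robustness to
real-data features the generator omits — uneven gene density along a
chromosome, chromosome-scale compartment structure in the contact map,
missing/filtered Hi-C bins (supported by the loaders and distance code
but not generated by default), identifier mismatch between group
databases and the gene table, and the heavy size skew of curated pathway
collections.

## Pipeline and reproducibility

`run_analysis` executes, per group collection: load → tandem merge →
restriction of groups to mapped genes → the selected tests.  One batch of
permutation replicates per (collection, scheme) feeds all scalar tests,
tail tests and per-group empirical p-values, so a report is reproducible
from config + seed alone; reports are byte-identical across reruns and
carry no timestamps.  Raw p-values are always emitted; family-wise
correction across the test battery is left to the user (a deliberate
choice: the natural test family depends on the study), while the tail
test's Bonferroni-by-j correction is built in.  Undefined per-group
entries are written as `NA`, never zero-filled.

## Known limitations

* With very few chromosomes, chromosome-count statistics are coarsely
  discrete and their permutation tests mildly conservative (rejection at
  α = 0.05 runs ~1–2 points below nominal in the 2-chromosome reference
  condition).
* Pair distances inherit the segment grid, so collections whose pairs hit
  few distinct segment pairs can tie heavily; the quantile binning then
  refuses to build 20 bins and reports the offending quantiles rather
  than testing on degenerate bins.
* The within-chromosome scheme conditions on the observed chromosome
  assignment; it has no power against dispersal, by design.
* Monte-Carlo p-values are bounded below by 1/(n+1); choose n for the
  resolution required.
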