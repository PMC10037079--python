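# Methods

This note documents the models, conventions and numerical choices behind
`svpopgen`, and what the synthetic cohort does and does not emulate.

## The synthetic cohort

### Population model

Allele frequencies follow the Balding–Nichols model. Each locus draws an
ancestral frequency `p ~ Uniform(0.05, 0.95)` (the bounds avoid effectively
monomorphic draws; configurable). Each population with drift parameter
`F ∈ [0, 1)` draws its frequency from `Beta(p(1−F)/F, (1−p)(1−F)/F)`, whose
mean is `p` and whose variance is `F·p(1−p)`; `F = 0` degenerates to the
ancestral frequency. Genotypes are `Binomial(2, p_pop)` per diploid sample.
Under this model expected heterozygosity scales as `(1−F)·2p(1−p)`, which is
the quantitative hook used by the diversity tests.

The default cohort mirrors a three-continent invasion design at 49 samples:

| deme | n | F | batch | role |
|---|---|---|---|---|
| UK | 8 | 0.03 | b1 | native source |
| NA | 8 | 0.08 | b1 | invasive |
| AU_EAST | 12 | 0.12 | b2 | invasive |
| AU_SOUTH | 12 | 0.12 | b2 | invasive |
| MUNG | 9 | 0.40 | b2 | extreme-drift range edge |

The `F` values are chosen to give a clearly structured cohort with one
strongly drifted deme; they are simulation knobs, not estimates.

### Genome, positions, and the shared density field

The genome is three chromosomes totalling 4.5 Mb with random sequence,
non-overlapping gene spans (10/Mb, 0.5–5 kb) and repeat intervals
(300/Mb, 50–500 bp ≈ 8 % of the genome, a realistic repeat content for a
passerine-sized assembly scaled down; classes: simple, low-complexity,
LINE, LTR, unclassified with simple repeats the majority).

SNP and SV positions are both drawn from one latent log-normal density
field (100-kb tiles, log-sd 0.6). This shared driver is what makes windowed
SNP and SV densities genuinely correlated, as they are in real genomes;
without it the density regression would have nothing to find. SV positions
are additionally enriched in subtelomeric windows (terminal 10 % of each
chromosome, multiplier 3 by default) by accept–reject on top of the field.

Default variant numbers are 20,000 SNPs (≈ 4.4/kb — the same order as a
high-density whole-genome callset scaled to 4.5 Mb) and 300 SVs. SV density
is deliberately above the per-Mb rate of a real cohort so the SV-side
statistics have workable sample sizes on a desk-scale genome; only relative
SNP-vs-SV patterns are interpreted. SV type weights (DEL 0.45, TRA 0.25,
DUP 0.18, INV 0.07, INS 0.05) reproduce the usual ordering: deletions most
common, inversions and insertions rare. TRA records are single break ends
with no length; INS occupy their insertion point.

True SV start coordinates are kept ≥ 2.5 kb apart. This guarantees that
distinct true loci can never fall within the 1-kb merge radius of each
other, which is what makes exact truth recovery a well-defined oracle for
the consensus merge. Real data offer no such guarantee; the merge handles
colliding loci deterministically, but "exactly equals truth" is a property
of this simulator setting, not of real callsets.

### Planted selection signals

* **Divergent loci** (20 by default): native frequency drawn low
  (0.02–0.15), all invasive demes high (≥ 0.6 above it), direction
  randomised — so `|Δp| ≥ 0.6` holds by construction.
* **Balanced clusters** (3 by default): a core SNP at folded frequency 0.4
  with 12 companion SNPs within ±1 kb whose folded frequencies lie within
  0.05 of the core's, identical across populations (balancing selection
  maintains the polymorphism everywhere). With
  `balanced_frac_upstream_dels > 0`, that fraction of clusters is confined
  to the 1-kb window immediately upstream of a randomly chosen DEL — the
  designed configuration for the SV pseudo-β contrast.
* **Invader-specific SVs** (`floor(0.15 · n_svs)` by default): frequency
  forced to 0 in the native deme and drawn low (0.02–0.3) in the others,
  emulating variants that arose after introduction.

Two ascertainment guarantees are imposed on SV genotypes: every labelled
invader-specific SV carries ≥ 1 alternate allele in the core invasive
demes, and every unlabelled SV carries ≥ 1 in the native deme. This mimics
discovery across the full cohort and makes the truth labels recoverable
exactly by the extraction rule; it slightly perturbs the lowest allele
frequencies.

With `sv_invader_admixture = true`, invasive demes draw their SV (not SNP)
frequencies as the mean of two independent Balding–Nichols draws at the
native `F` — two introductions of source stock. Averaging halves the drift
variance, so invader SV diversity is expected at or above the source's while
invader SNP diversity stays depressed; this is the designed configuration
for the diversity-reversal property.

### Pseudo-callers

Three caller profiles emit per-sample VCFs. A caller reports a call only
for carriers (dosage ≥ 1), with probability `detect_prob` (optionally per
SV type); the reported interval is shifted by a uniform jitter in
`±pos_jitter_bp` (jitter < 1,000 bp so replicate calls stay mergeable;
the shift is clamped so intervals stay on the chromosome and SVLEN is
preserved); the genotype flips between 0/1 and 1/1 with
`genotype_error_rate`; FILTER is PASS with `pass_filter_prob`, else
LowQual. False positives arrive as a Poisson process per Mb with random
type, length and genotype. Optional batch-keyed dropout removes a true SV
from every caller of an affected sample, emulating batch-dependent SV loss
(the batch-effect screen's designed signal). What is **not** modelled:
reads, mapping, depth, caller-specific biases beyond these rates — so tests
passing here say nothing about, e.g., depth-dependent genotype error in
real data.

Randomness: one seed; every operation draws from a named substream
(`default_rng([seed, crc32(name)])`), so adding false positives does not
shift genotype draws, and identical configurations reproduce outputs byte
for byte.

## Consensus merging

Pairwise compatibility between calls: same chromosome, same type and strand
(when required), same genotype (per-sample stage only), distinct
callers/samples, and distance ≤ 1,000 bp, where distance is
`max(|Δstart|, |Δend|)` when both calls have ends, else `|Δstart|`. Calls
shorter than 30 bp are excluded; TRA break ends have no length and are
never length-filtered.

Clustering is defined by an objective rather than an incremental heuristic.
Within each connected component (single-linkage reachability), the chosen
partition into pairwise-compatible clusters (1) retains the most calls —
a call is retained when its cluster has ≥ `min_support` distinct callers —
(2) uses the fewest clusters, (3) minimises total intra-cluster pairwise
distance, and breaks remaining ties lexicographically. Components of ≤ 10
calls are solved exactly by enumerating valid partitions; larger components
(essentially only cross-sample loci shared by many samples) use a
deterministic greedy clique-growing pass. An exhaustive oracle implements
the same objective by full Bell-partition enumeration and defines
correctness on small instances; the fast path must match it exactly.
The distance tie-break also resolves the two-calls-from-one-caller
conflict: the nearer call joins the cluster, the farther one is left to an
unsupported singleton.

Representative coordinates are per-coordinate lower medians of the members.
Where retained clusters from different genotype partitions collide within
1 kb at one locus (possible under jitter), the cluster with more supporting
callers wins, then the smaller coordinate. Cross-sample, a sample with no
member call is typed 0/0 (absence-as-reference, so MAF and missingness are
well defined on the merged set); a missing-genotype convention is available.

## Filters

MAF filtering retains sites with MAF ≥ 0.03 (the "at least" convention of
the standard tools). LD pruning is sequential and first-retained-wins:
scanning in position order, a site is removed if its genotype r² (composite
dosage correlation — no phase is available) with any previously retained
site within 1,000 bp exceeds 0.6; zero-variance pairs count as r² = 0.
Thinning keeps a site iff it is **more than** 5,000 bp after the last kept
site. Kinship is KING-robust,
`φ = (N_het,het − 2·N_opp_hom)/(N_het,i + N_het,j)` over jointly called
sites, flagged at φ ≥ 0.25. Mean-depth filters used on real callsets are
inapplicable (no depths are simulated) and logged as skipped.

## Landscape

Windows tile each chromosome from 0 at a fixed size; the default analysis
uses 100-kb windows — the desk-scale analogue of 1-Mb windows on a Gb-scale
genome, keeping the windows-per-genome count comparable. SNPs are counted by
position; SVs by coverage (every window their interval overlaps), so summed
SV counts can exceed the record count; TRA count at their break end. The
regression is a Poisson log-link GLM of SV count on SNP count with
dispersion estimated by Pearson χ²/df (quasipoisson: identical point
estimates, inflated standard errors); the reported t is coefficient over
quasi-SE, residuals are deviance residuals (Pearson available). An all-zero
response is reported as a degenerate fit with zero residuals. Subtelomeric
vs interior residuals are compared by mean difference plus a two-sided
rank-sum test; the summary is omitted when either class has < 2 windows.

Break-end repeat classification intersects the 30-bp window starting at the
SV's first break end with the repeat annotation; the class with the largest
overlap wins, ties resolved toward the earlier interval. This replaces a
homology search with annotation overlap: in the synthetic setting the
repeat BED is ground truth, so the 30-bp rule itself is what is tested.
Size classes for the gene-overlap table are 1 bp (SNP), [30, 100),
[100, 1 k), [1 k, 10 k), ≥ 10 kb; TRA break ends have no size and are
excluded. Whole gene spans (not exons) define overlap.

## Diversity

Per site within a population with `n` non-missing alleles, `j` of them
alternate: `H_O` = het genotypes / called genotypes;
`H_E = 1 − p² − q²` with `p = j/n`; `π = 2j(n−j)/(n(n−1))`, the unbiased
expected pairwise difference, so `π = H_E · n/(n−1)` identically.
Population values are means over all retained sites — variant-site
averaging, since the input is a variant-only callset; only relative
cross-population patterns are interpreted. A private allele is an allele
(reference or alternate) observed in exactly one of the compared
populations; counts are not rarefied, so unequal sample sizes bias them
(documented caveat). The folded SFS uses minor-allele frequencies in fixed
0.05 bins over (0, 0.5], exactly 0.5 in the top bin, monomorphic sites in
the lowest bin so class histograms sum to class sizes. Gene-overlap SFS
classes: complete (SV contains a whole gene), break-end (an SV edge inside
a gene), none.

PCA standardises dosages per site by `2p̂` and `sqrt(2p̂(1−p̂))`
(mean-imputed missing entries, zero-variance sites dropped) and
eigendecomposes the sample covariance; each component's largest-magnitude
site loading is made positive so coordinates are reproducible.

## Selection

F_ST is the Weir–Cockerham (1984) genotype-based θ with the heterozygosity
terms; loci monomorphic across both groups are undefined. The outlier
threshold is empirical: the multi-locus θ (ratio of summed components,
floored at 1e-4) and the observed minor-allele-frequency pool parameterise
a Balding–Nichols null; 5,000 pseudo-observed loci are simulated at the
observed group sample sizes and the scan threshold is their 99th
percentile; observed loci (θ floored at 0) above it are flagged. On fully
neutral data the flagged fraction is ~1 % by construction; a single
dataset's fraction carries extra variance beyond binomial because the
5,000-locus threshold itself is a Monte-Carlo quantile (about nine in ten
seeds land inside the exact binomial band). The two native-vs-invader-
subgroup contrasts are scanned separately and their flag sets unioned.

The β(1) statistic uses, for a core at folded frequency `f_c` with `n`
alleles: `θ_W = S/a_n` with `S` the count of other polymorphic sites within
±1 kb and `a_n = Σ_{k<n} 1/k`; and `θ_β = Σ_i g(f_i)/b_n(f_c)` with kernel
`g(f) = (1 − |f − f_c|/M_c)²`, `M_c = max_k |k/n − f_c|` over folded
classes, and `b_n(f_c) = Σ_k g(k/n)·c_{n,k}`,
`c_{n,k} = (1/k + 1/(n−k))/(1 + [k = n−k])`. Because
`Σ_k c_{n,k} = a_n`, the normaliser makes `E[θ_β] = θ` under the neutral
folded SFS, so β(1) is mean-zero on neutral data by construction — the
property the tests verify. Cores require folded frequency ≥ 0.15
(low-frequency cores mostly reflect drift); empty windows score 0 with an
S = 0 flag; fewer than 4 alleles is refused. This is a self-contained
folded similarity-kernel statistic: it follows the same θ_β-vs-θ_W design
as published balancing-selection scans but equivalence to any external
implementation is not claimed.

Pseudo-β(1) per SV collects SNP scores with position in
`[breakend − 1000, breakend)` — half-open, lower-coordinate side of the
first break end, strand ignored — and takes the 0.1-trimmed mean
(`floor(0.05·k)` values dropped per tail, i.e. the middle 90 %; for k < 20
nothing is trimmed and the value equals the plain mean). SVs with no
upstream score are excluded from group comparisons and counted. A pooled
mode emits the raw collected scores instead.

The seven-group contrast (outlier SNPs, non-outlier SNPs, outlier SVs,
non-outlier DEL/DUP/TRA/INV) uses tie-corrected Kruskal–Wallis and Dunn's
pairwise z-tests on the pooled ranks with Benjamini–Hochberg adjustment
(Holm/Bonferroni selectable; the adjustment method is a choice, not a
given). Groups with fewer than two members are dropped with a warning —
the same rule that removes a variant class observed once.

## Problem sizes

The shipped analyses run on one CPU in well under a minute each: the
default study is 20,000 SNPs / 300 SVs / 49 samples; calibration
experiments use 10,000-locus datasets with 24 + 24 samples and 5,000-locus
pseudo-observed thresholds; replicate-based checks use 2,500-SNP studies
(100 replicates for the subtelomere detection rate, 20 seeds for
β-cluster power). These sizes were chosen so that every Monte-Carlo
assertion has comfortable resolution while the whole suite stays fast.

## Known limitations

* No coalescent, no recombination, no mutation process: frequencies are
  exchangeable across loci given the field, so LD beyond the planted
  clusters is absent. LD pruning is therefore exercised mostly by planted
  duplicates and near-duplicates in tests.
* The per-sample/per-caller emulation has no read-level error structure;
  genotype errors are symmetric 0/1↔1/1 flips.
* Variant-site averaging makes H/π magnitudes incomparable to per-bp
  genome-wide values; only cross-population contrasts are meaningful.
* The greedy fallback for merge components larger than 10 calls is
  deterministic but not provably objective-optimal; in simulated cohorts
  such components are almost exclusively cross-sample stacks of one locus,
  where the greedy and exact answers coincide.
* Private-allele counts are not rarefied across unequal sample sizes.
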