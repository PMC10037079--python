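# svpopgen

Comparative population genomics of SNPs and structural variants (SVs) for
invasion-biology study designs, exercised end to end on a built-in synthetic
cohort generator.

## The problem

Invasive populations diverge from their source within decades. Whole-genome
studies of such systems increasingly contrast two variant classes — SNPs and
structural variants (deletions, duplications, inversions, insertions and
translocation break ends) — because the two can tell different stories about
diversity, drift and selection. Doing that comparison well requires a chain
of specialised steps that are usually scattered across a dozen tools:

1. **Genotype-aware consensus SV merging.** Short-read SV callers have high
   false-positive rates, so calls from three callers are merged per sample:
   calls merge only if their break ends lie within 1 kb, their type and
   strand agree, **and the callers agree on the sample's genotype** (the
   merge is run separately within each genotype partition). Per-sample
   consensus calls are then merged across samples (support 1, no genotype
   requirement) into one cohort callset.
2. **Dataset filtering.** Missingness ≤ 0.5 and MAF ≥ 0.03; LD pruning at
   r² > 0.6 within 1 kb; physical thinning to > 5 kb; a KING-robust kinship
   screen for full siblings (φ ≥ 0.25).
3. **Density landscapes.** SNP and SV counts in fixed windows; a
   quasipoisson GLM of SV count on SNP count; residual comparison of
   subtelomeric vs interior windows; gene overlap by variant size class;
   repeat classification of SV break ends from their first 30 bp.
4. **Diversity.** H_O, H_E and π per population (computed identically for
   SNPs and SVs, treating SV carriage as a biallelic allele), private
   alleles, folded SFS split by gene-overlap class, invader-specific
   variant extraction, PCA.
5. **Selection.** Weir–Cockerham F_ST outlier scanning with an empirical
   threshold calibrated on 5,000 pseudo-observed neutral loci (99th
   percentile); a folded β(1) balancing-selection scan
   (β(1) = θ_β − θ_W, where θ_β weights nearby SNPs by folded-frequency
   similarity to the core and θ_W is Watterson's estimator); SV-level
   pseudo-β(1) as the 0.1-trimmed mean of SNP scores within 1 kb upstream
   of the first break end; and a seven-group Kruskal–Wallis/Dunn contrast
   of outlier and non-outlier SNPs and SV types.

`svpopgen` implements this whole chain as a library, together with a
seed-reproducible generator (`svpopgen.simulate`) that emulates the study
inputs — genome, annotations, population-structured truth variants under the
Balding–Nichols model, and three imperfect pseudo-callers — so every stage
is testable without any sequencing data.

## Worked example

Each script in `examples/` is a small narrative for one capability. For
instance the selection scans (`python examples/06_selection_scans.py`):

```
fitted null F_ST = 0.085; POD 1% threshold = 0.522
flagged outliers: 58 of 4039 (23 of the 25 planted divergent loci)

beta(1) cores scored: 2817; planted balanced cores score 3.26 vs neutral median 0.00
SVs with upstream SNP scores: 51 of 100; mean pseudo-beta 0.23
```

The scan fits the neutral null from the data itself (multi-locus F_ST
0.085), simulates 5,000 neutral loci, and flags observed loci above the
simulated 99th percentile: 23 of 25 planted divergent loci are recovered
while the genome-wide flag rate stays near 1%. Planted balanced clusters
(companion SNPs at matched folded frequencies within ±1 kb of a core) score
far above the neutral β(1) median of ≈ 0.

The density landscape (`python examples/04_density_landscape.py`):

```
45 windows; GLM slope 8.03e-03 (t = 6.02, dispersion 1.66)
mean residual: subtelomeric +1.67 vs interior -0.62 (rank-sum p = 2.8e-06)
```

SV density tracks SNP density overall (positive t), but chromosome ends
carry more SVs than SNP density predicts — the planted subtelomeric
enrichment is recovered in the residuals.

There is also a thin CLI over the same pipeline:

```bash
svpopgen all --seed 1 --outdir run1        # simulate → merge → … → selection
svpopgen validate-config --config my.yaml
```

Re-running any command with the same seed and configuration reproduces every
output byte for byte.

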