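"""Generate a complete simulated study bundle and summarize what it contains.

The generator emulates a multi-continent invasion cohort: 49 diploid samples
in five demes (a native source, three invasive demes, one extreme-drift
range-edge deme) on a small three-chromosome genome, with SNPs and SVs whose
allele frequencies follow Balding-Nichols drift, and three imperfect SV
callers producing per-sample VCFs.
"""

from svpopgen.simulate import SimConfig, Simulation

config = SimConfig(seed=1, n_snps=4000, n_svs=150)
manifest = Simulation(config).write("scratch_example_run")

genome, truth, calls = Simulation(config).run()
print(f"genome: {config.n_chrom} chromosomes, {sum(config.chrom_lengths) / 1e6:.1f} Mb")
print(f"genes: {len(genome.genes)}, repeat intervals: {len(genome.repeats)}")
print(f"true SNPs: {len(truth.snps)}, true SVs: {len(truth.svs)}")
print(f"SV types: {({str(k): int(v) for k, v in truth.svs['type'].value_counts().items()})}")
print(f"invader-specific SVs (absent from the native range): "
      f"{int(truth.svs['invader_specific'].sum())}")
n_calls = sum(len(v) for v in calls.values())
print(f"caller VCF records across 49 samples x 3 callers: {n_calls}")
print(f"files written: {len(manifest)} (FASTA, GFF3, BED, VCFs, truth tables)")
# Counts above are the ground truth each downstream stage is tested against.
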