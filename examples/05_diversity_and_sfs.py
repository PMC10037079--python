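"""Per-population diversity, invader-specific variants, and the folded SFS.

H_O, H_E and pi are computed identically for SNPs and SVs (an SV's alternate
allele is carriage of the variant), so the two variant classes can be
contrasted across populations.  Invader-specific SVs are those absent from
the native range; common ones (MAF > 0.15) are candidates for post-
introduction evolution.
"""

import numpy as np

from svpopgen.diversity import (classify_gene_overlap, common_filter, diversity,
                                folded_sfs, invader_specific)
from svpopgen.simulate import SimConfig, Simulation
from svpopgen.vcfio import build_matrix

config = SimConfig(seed=4, n_snps=3000, n_svs=200)
genome, truth, _ = Simulation(config).run()
popmap = truth.population_map()
sv_matrix = build_matrix(truth.sv_records(), popmap)

print(diversity(sv_matrix).to_string(index=False, float_format="%.3f"))
print("MUNG (the extreme-drift range edge) should show the lowest diversity")

excluded = list(truth.samples.loc[truth.samples["role"] == "range_edge", "sample"])
inv = invader_specific(sv_matrix, ["NA", "AU_EAST", "AU_SOUTH"], excluded)
common = common_filter(inv, sv_matrix)
print(f"\ninvader-specific SVs: {len(inv)}; common (MAF > 0.15): {len(common)}")

labels = classify_gene_overlap(truth.sv_records(), genome.genes)
sfs = folded_sfs(sv_matrix, labels)
totals = sfs.groupby("class")["count"].sum()
print("\nfolded SFS class sizes (gene-overlap classes partition the SV set):")
print(totals.to_string())
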