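"""Genotype-aware consensus SV merging on a hand-built example.

Three callers report a deletion near 10 kb for one sample.  Two agree on the
heterozygous genotype and lie within 1 kb of each other, so they form a
consensus call; the third caller reports a homozygous genotype and is left
out — the genotype-agreement rule treats it as a different assertion about
the sample.
"""

from svpopgen.merge import MergeParams, merge_per_sample
from svpopgen.vcfio import VariantRecord


def deletion(pos, caller, gt):
    return VariantRecord("chr1", pos, "DEL", {"sample1": gt}, end=pos + 499,
                         length=500, strands="+-", caller=caller,
                         variant_id=f"{caller}@{pos}")


callsets = [
    [deletion(10_000, "lumpy-like", gt=1)],
    [deletion(10_400, "delly-like", gt=1)],
    [deletion(10_200, "manta-like", gt=2)],  # genotype disagrees
]
consensus = merge_per_sample(callsets, MergeParams(), sample="sample1")
for c in consensus:
    print(f"consensus {c.sv_type} at {c.chrom}:{c.pos}-{c.end} "
          f"GT={c.genotypes['sample1']} supported by {sorted(c.support['sample1'])}")
print("the genotype-discordant caller is not part of the consensus;")
print("with all three discordant, the site would be dropped entirely.")
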