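"""Whole-genome doubling, arm events and aneuploidy score for one sample.

Builds a toy profile by hand: chromosome 7 gained on both arms, chromosome
10 lost on both arms, everything else balanced diploid, plus one focal
amplification and one homozygous deletion.
"""

import pandas as pd

from tumorcomplexity import SegmentProfile, grch37_build, ploidy_report

build = grch37_build()
rows = []
for chrom, length in build.chrom_lengths.items():
    if chrom == "7":
        rows.append((chrom, 1, length, 3, 1))       # whole-chromosome gain
    elif chrom == "10":
        rows.append((chrom, 1, length, 1, 0))       # whole-chromosome loss
    elif chrom == "5":
        rows.append((chrom, 1, 1_000_000, 8, 1))    # focal amplification
        rows.append((chrom, 1_000_001, length, 2, 1))
    elif chrom == "9":
        rows.append((chrom, 1, 500_000, 0, 0))      # homozygous deletion
        rows.append((chrom, 500_001, length, 2, 1))
    else:
        rows.append((chrom, 1, length, 2, 1))
profile = SegmentProfile(
    "toy", pd.DataFrame(rows, columns=["chrom", "start", "end", "total_cn", "minor_cn"]),
    ploidy=2.0, purity=0.9,
)

rep = ploidy_report(profile, build)
print(f"wgd                     : {rep.wgd}")
print(f"wgd_fraction            : {rep.wgd_fraction:.4f}")
print(f"aneuploidy_score        : {rep.aneuploidy_score}")
print(f"altered_genome_fraction : {rep.altered_genome_fraction:.4f}")
print(
    "\nThe aneuploidy score counts autosomal arms gained or lost relative to"
    "\nploidy (both arms of 7 and of 10 here -> 4, out of a maximum of 39);"
    "\nthe altered fraction is the genome length in amplification (CN>=6),"
    "\nCN1 loss, CN0 deletion or copy-neutral LOH."
)
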