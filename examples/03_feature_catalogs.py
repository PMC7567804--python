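"""Build the SBS96, SV32 and CN40 feature catalogs for one simulated sample.

Simulates a sample on a small genome, counts its SNVs into trinucleotide
classes against the emitted reference, clusters rearrangement breakpoints
and bins events into the 32 rearrangement categories, and classifies
copy-number segments into the 40-category scheme.
"""

from pathlib import Path

from tumorcomplexity import (
    SimulationConfig,
    build_sbs96,
    classify_cn40,
    classify_sv32,
    cluster_breakpoints,
    mini_build,
    simulate_sample,
)
from tumorcomplexity.feature_catalogs import CN40_LABELS, SBS96_LABELS, SV32_LABELS
from tumorcomplexity.genome_io import write_fasta

cfg = SimulationConfig(seed=11, genome=mini_build().scaled(0.1, "micro"), snv_count=400)
profile, rearr, snvs, reference, truth = simulate_sample(cfg, 0)

Path("example_out").mkdir(exist_ok=True)
fa = Path("example_out/reference_micro.fa")
write_fasta({c: s.decode() for c, s in reference.items()}, fa)

sbs, excluded = build_sbs96(snvs, fa)
flags = cluster_breakpoints(rearr, distance_d=1e6, min_cluster_size=10)
sv = classify_sv32(rearr, flags)
cn = classify_cn40(profile)

print(f"SNVs counted: {sbs.sum()} (excluded: {excluded}); top SBS96 classes:")
for i in sbs.argsort()[::-1][:3]:
    print(f"  {SBS96_LABELS[i]:<10} {sbs[i]}")
print(f"\nrearrangements: {sv.sum()} ({int(flags.sum())} clustered); top SV32 classes:")
for i in sv.argsort()[::-1][:3]:
    print(f"  {SV32_LABELS[i]:<28} {sv[i]}")
print(f"\nsegments: {cn.sum()}; top CN40 classes:")
for i in cn.argsort()[::-1][:3]:
    print(f"  {CN40_LABELS[i]:<24} {cn[i]}")
print(
    "\nEach column sums to the number of SNVs / events / segments in the"
    "\nsample; these count vectors are the input to signature inference."
)
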