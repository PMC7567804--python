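"""Sample- and locus-level annotations.

Tumor mutational burden, gene-level amplification / homozygous-deletion
calls, TERT-upstream breakpoints with super-enhancer proximity, the
normalized telomere-length log2 ratio, and descriptive 1-Mb breakpoint
recurrence binning across a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import (
    ConfigError,
    GenomeBuild,
    IntervalTrack,
    RearrangementSet,
    SegmentProfile,
    normalize_chrom,
)

__all__ = [
    "SampleSummary",
    "TertAnnotation",
    "compute_tmb",
    "TMB_HIGH_THRESHOLD",
    "gene_cn_status",
    "annotate_tert_breakpoints",
    "telomere_ratio",
    "bin_breakpoints_1mb",
]

TMB_HIGH_THRESHOLD = 20.0  # mutations/Mb
AMPLIFICATION_CN = 6
TERT_UPSTREAM_WINDOW = 20_000
SE_PROXIMITY = 100_000
BIN_SIZE = 1_000_000


@dataclass
class SampleSummary:
    sample_id: str
    tmb: float
    rearrangement_count: int
    wgd: bool
    aneuploidy_score: int
    altered_genome_fraction: float


@dataclass
class TertAnnotation:
    sample_id: str
    breakpoint_pos: int
    distance_to_tert_start: int
    partner_chrom: str
    partner_pos: int
    se_distance: int
    se_proximal: bool


def compute_tmb(snv_indel_count: int, genome_size_mb: float) -> float:
    """Mutations (SNV/DNV/TNV/indel) per megabase."""
    if genome_size_mb <= 0:
        raise ConfigError("genome size must be > 0 Mb")
    return snv_indel_count / genome_size_mb


def gene_cn_status(profile: SegmentProfile, genes: IntervalTrack) -> pd.DataFrame:
    """Per-gene copy-number status.

    A gene is amplified when any overlapping segment has total CN >= 6 and
    homozygously deleted when any overlapping segment has total CN 0; a gene
    spanning both kinds of segment reports both.  Returns a table with
    boolean ``amplified`` / ``homdel`` columns and a ``status`` summary.
    """
    seg = profile.segments
    rows = []
    for g in genes.intervals.itertuples():
        over = seg[
            (seg["chrom"] == g.chrom) & (seg["end"] >= g.start) & (seg["start"] <= g.end)
        ]
        amp = bool((over["total_cn"] >= AMPLIFICATION_CN).any())
        hd = bool((over["total_cn"] == 0).any())
        if amp and hd:
            status = "amplified+homdel"
        elif amp:
            status = "amplified"
        elif hd:
            status = "homdel"
        else:
            status = "none"
        rows.append((g.label, g.chrom, g.start, g.end, amp, hd, status))
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "amplified", "homdel", "status"]
    ).set_index("gene")


def _gap_distance(pos: int, start: int, end: int) -> int:
    """Unsigned gap between a point and an interval (0 when inside)."""
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0


def annotate_tert_breakpoints(
    rearr: RearrangementSet,
    tert_locus: tuple,
    se_track: IntervalTrack,
    window: int = TERT_UPSTREAM_WINDOW,
    se_proximity: int = SE_PROXIMITY,
) -> list:
    """Annotate breakpoint pairs with one end just upstream of TERT.

    ``tert_locus`` is ``(chrom, start, end, strand)``.  The upstream window
    is the ``window`` bp 5' of the gene start on its coding strand (TERT is
    minus-strand on GRCh37, so upstream means higher coordinates).  For each
    qualifying breakpoint the partner end's minimum gap distance to any
    super-enhancer is computed; ``se_proximal`` is true within
    ``se_proximity`` bp.
    """
    chrom, start, end, strand = tert_locus
    chrom = normalize_chrom(chrom)
    if strand == "+":
        win_lo, win_hi = start - window, start - 1
        tss = start
    else:
        win_lo, win_hi = end + 1, end + window
        tss = end
    se = se_track.intervals
    out = []
    for r in rearr.events.itertuples():
        for bp_chrom, bp_pos, pt_chrom, pt_pos in (
            (r.chrom1, r.pos1, r.chrom2, r.pos2),
            (r.chrom2, r.pos2, r.chrom1, r.pos1),
        ):
            if bp_chrom != chrom or not (win_lo <= bp_pos <= win_hi):
                continue
            partner_se = se[se["chrom"] == pt_chrom]
            if len(partner_se):
                dists = [
                    _gap_distance(pt_pos, s, e)
                    for s, e in zip(partner_se["start"], partner_se["end"])
                ]
                se_dist = int(min(dists))
            else:
                se_dist = np.iinfo(np.int64).max
            out.append(
                TertAnnotation(
                    sample_id=rearr.sample_id,
                    breakpoint_pos=int(bp_pos),
                    distance_to_tert_start=int(abs(bp_pos - tss)),
                    partner_chrom=pt_chrom,
                    partner_pos=int(pt_pos),
                    se_distance=se_dist,
                    se_proximal=se_dist <= se_proximity,
                )
            )
    return out


def telomere_ratio(
    tumor_reads: float, tumor_mean_cov: float, normal_reads: float, normal_mean_cov: float
) -> float:
    """Relative telomere length as a coverage-normalized log2 ratio.

    Telomeric-repeat read counts are normalized to mean genomic coverage in
    tumor and matched normal; the statistic is
    log2((tumor_reads / tumor_cov) / (normal_reads / normal_cov)).
    """
    for v in (tumor_reads, tumor_mean_cov, normal_reads, normal_mean_cov):
        if v <= 0:
            raise ConfigError("telomere_ratio inputs must all be > 0")
    return float(
        np.log2((tumor_reads / tumor_mean_cov) / (normal_reads / normal_mean_cov))
    )


def bin_breakpoints_1mb(
    cohort_rearrangements: list,
    build: GenomeBuild,
    bin_size: int = BIN_SIZE,
) -> pd.DataFrame:
    """Count, per 1-Mb genome bin, the samples with a breakpoint in the bin.

    The genome is tiled half-open from position 1 (bin i covers
    [i*bin_size + 1, (i+1)*bin_size]); every breakpoint end falls in exactly
    one bin.  Returns chrom / bin_start / bin_end / n_samples rows.
    """
    lengths = build.chrom_lengths
    per_bin: dict = {}
    for rearr in cohort_rearrangements:
        ends = rearr.breakpoint_ends()
        for r in ends.itertuples():
            if r.chrom not in lengths:
                continue
            b = (int(r.pos) - 1) // bin_size
            per_bin.setdefault((r.chrom, b), set()).add(rearr.sample_id)
    rows = []
    for chrom in build.chrom_names:
        n_bins = int(np.ceil(lengths[chrom] / bin_size))
        for b in range(n_bins):
            samples = per_bin.get((chrom, b), set())
            rows.append(
                (
                    chrom,
                    b * bin_size + 1,
                    min((b + 1) * bin_size, lengths[chrom]),
                    len(samples),
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end", "n_samples"])
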