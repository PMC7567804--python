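"""Whole-genome doubling, arm-level events, aneuploidy score, altered fraction.

All computations are restricted to the autosomal genome and are
length-weighted over segment lengths.  Decision thresholds are strict
inequalities: WGD requires a major copy number >= 2 over *more than* 50% of
the autosomal segment length, and an arm call requires *more than* 80% of
the arm's covered length altered in one direction relative to sample ploidy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .genome_io import (
    GenomeBuild,
    InsufficientDataError,
    SegmentProfile,
    split_at_arms,
)

__all__ = [
    "ArmCallTable",
    "PloidyReport",
    "call_wgd",
    "call_arm_events",
    "aneuploidy_score",
    "altered_genome_fraction",
    "ploidy_report",
]

WGD_FRACTION_THRESHOLD = 0.5
ARM_FRACTION_THRESHOLD = 0.8
AMPLIFICATION_CN = 6


@dataclass
class ArmCallTable:
    """Per-arm gain/loss calls over the counted autosomal arms."""

    calls: pd.DataFrame  # index arm name; call, altered_fraction_gain/loss

    def __post_init__(self):
        c = self.calls
        assert set(c["call"].unique()) <= {"gain", "loss", "neutral"}

    def altered_arms(self) -> list:
        return list(self.calls.index[self.calls["call"] != "neutral"])


@dataclass
class PloidyReport:
    wgd: bool
    wgd_fraction: float
    aneuploidy_score: int
    altered_genome_fraction: float


def call_wgd(profile: SegmentProfile) -> tuple:
    """Call whole-genome doubling.

    A tumor has undergone WGD when more than half of its autosomal genome
    (length-weighted over segments) has a major copy number — the most
    frequent allele — of at least two.  Returns ``(wgd, wgd_fraction)``.
    """
    seg = profile.autosomal()
    if seg.empty:
        raise InsufficientDataError("no autosomal segments")
    lengths = (seg["end"] - seg["start"] + 1).to_numpy(dtype=float)
    major = (seg["total_cn"] - seg["minor_cn"]).to_numpy()
    frac = float(lengths[major >= 2].sum() / lengths.sum())
    return frac > WGD_FRACTION_THRESHOLD, frac


def call_arm_events(
    profile: SegmentProfile, build: GenomeBuild, presplit: bool = False
) -> ArmCallTable:
    """Call each counted autosomal arm gained, lost or neutral.

    Each segment is gained / lost / neutral according to whether its total
    copy number is above / below / equal to the (unrounded) sample ploidy;
    an arm is called when more than 80% of its covered segment length is
    altered in the same direction.  Arms with no covered length are neutral.
    """
    if not presplit:
        profile = split_at_arms(profile, build)
    seg = profile.autosomal()
    rows = []
    for arm in build.counted_arms():
        s = seg[
            (seg["chrom"] == arm.chrom)
            & (seg["start"] >= arm.start)
            & (seg["end"] <= arm.end)
        ]
        lengths = (s["end"] - s["start"] + 1).to_numpy(dtype=float)
        covered = lengths.sum()
        if covered == 0:
            warnings.warn(f"arm {arm.name}: no covered length; calling neutral")
            rows.append((arm.name, "neutral", 0.0, 0.0))
            continue
        total = s["total_cn"].to_numpy(dtype=float)
        f_gain = float(lengths[total > profile.ploidy].sum() / covered)
        f_loss = float(lengths[total < profile.ploidy].sum() / covered)
        if f_gain > ARM_FRACTION_THRESHOLD:
            call = "gain"
        elif f_loss > ARM_FRACTION_THRESHOLD:
            call = "loss"
        else:
            call = "neutral"
        rows.append((arm.name, call, f_gain, f_loss))
    df = pd.DataFrame(
        rows, columns=["arm", "call", "altered_fraction_gain", "altered_fraction_loss"]
    ).set_index("arm")
    return ArmCallTable(df)


def aneuploidy_score(arm_calls: ArmCallTable) -> int:
    """Number of counted autosomal arms gained or lost (0..39 on GRCh37)."""
    return int((arm_calls.calls["call"] != "neutral").sum())


def altered_genome_fraction(profile: SegmentProfile) -> float:
    """Fraction of the autosomal genome with copy-number alteration.

    Altered states: amplification (total >= 6), single-copy loss (total 1),
    homozygous deletion (total 0) and copy-neutral LOH (total 2, minor 0).
    The denominator is the total autosomal segment length.
    """
    seg = profile.autosomal()
    if seg.empty:
        return 0.0
    lengths = (seg["end"] - seg["start"] + 1).to_numpy(dtype=float)
    total = seg["total_cn"].to_numpy()
    minor = seg["minor_cn"].to_numpy()
    altered = (
        (total >= AMPLIFICATION_CN)
        | (total == 1)
        | (total == 0)
        | ((total == 2) & (minor == 0))
    )
    return float(lengths[altered].sum() / lengths.sum())


def ploidy_report(profile: SegmentProfile, build: GenomeBuild) -> PloidyReport:
    """The full per-sample ploidy / aneuploidy summary."""
    wgd, frac = call_wgd(profile)
    arms = call_arm_events(profile, build)
    return PloidyReport(
        wgd=wgd,
        wgd_fraction=frac,
        aneuploidy_score=aneuploidy_score(arms),
        altered_genome_fraction=altered_genome_fraction(profile),
    )
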