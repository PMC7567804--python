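"""Kataegis detection and complex-chromosome (BFB / chromothripsis) calling.

Kataegis — localized hypermutation — is found by exact piecewise-constant
fitting of log10 inter-mutation distances (IMDs) per chromosome; a fitted
segment is a kataegis locus when it spans six or more consecutive mutations
whose mean raw IMD is at most 1 kb.

Chromosomes with localized complex rearrangements are first flagged as
candidates (non-random breakpoint distribution at p < 1e-5, a per-megabase
breakpoint-rate outlier with at least 35 breakpoints, or at least 10
translocations) and then classified from copy-number and breakpoint
evidence into BFB, chromothripsis, combined BFB/chromothripsis, or
localized complex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import (
    ConfigError,
    GenomeBuild,
    RearrangementSet,
    SegmentProfile,
    SnvSet,
)

__all__ = [
    "KataegisLocus",
    "ComplexChromosomeCall",
    "fit_pcf",
    "detect_kataegis",
    "detect_candidate_chromosomes",
    "classify_complex_chromosome",
    "classify_sample_complexity",
]

KATAEGIS_MIN_MUTATIONS = 6
KATAEGIS_MAX_MEAN_IMD = 1000.0
DEFAULT_PCF_GAMMA = 25.0

UNIFORMITY_P = 1e-5
RATE_MIN_BREAKPOINTS = 35
MIN_TRANSLOCATIONS = 10

FOLDBACK_SPAN = 30_000
CHROMOTHRIPSIS_MIN_SWITCHES = 10
CHROMOTHRIPSIS_MAX_STATES = 3
HET_RETENTION_MIN = 0.5
BFB_MIN_FOLDBACKS = 3
BFB_INV_TRA_FRACTION = 0.4


@dataclass(frozen=True)
class KataegisLocus:
    chrom: str
    start: int  # position of the first mutation in the locus
    end: int    # position of the last mutation
    n_mutations: int
    mean_imd: float


@dataclass
class ComplexChromosomeCall:
    sample_id: str
    chrom: str
    clustered_p: float
    rate_outlier: bool
    breakpoint_count: int
    translocation_count: int
    candidate: bool
    telomeric_loss: bool
    foldback_count: int
    inv_tra_fraction: float
    cn_switches: int
    cn_states: int
    het_retention_fraction: float
    call: str  # BFB | chromothripsis | BFB_chromothripsis | localized_complex | none


# ---------------------------------------------------------------------------
# Piecewise-constant fitting (exact DP) and kataegis
# ---------------------------------------------------------------------------


def fit_pcf(x: np.ndarray, gamma: float) -> list:
    """Exact least-squares segmentation of ``x`` with per-segment penalty.

    Minimizes sum over segments of (within-segment sum of squared deviations
    from the segment mean) + gamma, by O(n^2) dynamic programming.  Returns
    a list of (start, end) index pairs (inclusive) covering 0..n-1.
    """
    if gamma <= 0:
        raise ConfigError("PCF penalty gamma must be > 0")
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        return []
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    dp = np.empty(n + 1)
    dp[0] = 0.0
    back = np.empty(n, dtype=int)
    idx = np.arange(n)
    for j in range(1, n + 1):
        i = idx[:j]  # candidate segment starts for a segment ending at j-1
        length = j - i
        sse = (s2[j] - s2[i]) - (s1[j] - s1[i]) ** 2 / length
        cand = dp[i] + sse + gamma
        best = int(np.argmin(cand))
        dp[j] = cand[best]
        back[j - 1] = best
    segments = []
    j = n
    while j > 0:
        i = back[j - 1]
        segments.append((i, j - 1))
        j = i
    return segments[::-1]


def detect_kataegis(
    snvs: SnvSet, gamma: float = DEFAULT_PCF_GAMMA
) -> list:
    """Detect kataegis loci from a sample's SNVs.

    IMDs are computed within each chromosome on sorted positions and
    segmented on the log10 scale by exact PCF with penalty ``gamma``.  A
    locus is a run of six or more consecutive mutations contained in one
    fitted segment whose raw IMDs average <= 1000 bp; the run may be a
    proper sub-run of the segment, since the optimal segmentation can
    absorb a single long flanking IMD into a hypermutated segment (adding
    a one-point segment would cost a full penalty).
    """
    if gamma <= 0:
        raise ConfigError("PCF penalty gamma must be > 0")
    loci = []
    for chrom, grp in snvs.variants.groupby("chrom", sort=True):
        pos = np.sort(grp["pos"].to_numpy())
        if len(pos) < 2:
            continue
        imd = np.diff(pos).astype(float)
        x = np.log10(np.maximum(imd, 1.0))
        for i, j in fit_pcf(x, gamma):
            for a, b in _qualifying_runs(imd[i : j + 1]):
                n_mut = b - a + 2
                mean_imd = float(imd[i + a : i + b + 1].mean())
                loci.append(
                    KataegisLocus(
                        chrom, int(pos[i + a]), int(pos[i + b + 1]), n_mut, mean_imd
                    )
                )
    return loci


def _qualifying_runs(seg_imd: np.ndarray) -> list:
    """Maximal non-overlapping IMD runs with >= 6 mutations, mean <= 1 kb.

    Returns (start, end) index pairs (inclusive) into ``seg_imd``.  All
    windows of at least KATAEGIS_MIN_MUTATIONS - 1 IMDs are scanned
    (segments are short, so the quadratic scan is cheap) and the longest
    qualifying windows are kept greedily.
    """
    k = len(seg_imd)
    min_imds = KATAEGIS_MIN_MUTATIONS - 1
    if k < min_imds:
        return []
    csum = np.concatenate([[0.0], np.cumsum(seg_imd)])
    candidates = []
    for a in range(k - min_imds + 1):
        for b in range(a + min_imds - 1, k):
            mean = (csum[b + 1] - csum[a]) / (b - a + 1)
            if mean <= KATAEGIS_MAX_MEAN_IMD:
                candidates.append((b - a, a, b))
    chosen = []
    for _, a, b in sorted(candidates, reverse=True):
        if all(b < a2 or a > b2 for a2, b2 in chosen):
            chosen.append((a, b))
    return sorted(chosen)


# ---------------------------------------------------------------------------
# Candidate complex chromosomes
# ---------------------------------------------------------------------------


def _uniformity_p(pos: np.ndarray, length: int, method: str = "ks") -> float:
    """One-sample test of breakpoint positions vs Uniform(0, length)."""
    if len(pos) == 0:
        return 1.0
    if method == "ks":
        res = stats.kstest(pos, stats.uniform(loc=0, scale=length).cdf)
        return float(res.pvalue)
    if method == "chi2":
        nbins = max(int(length // 10_000_000), 2)
        obs, _ = np.histogram(pos, bins=nbins, range=(0, length))
        if len(pos) < nbins:  # too sparse for a chi-square
            return 1.0
        return float(stats.chisquare(obs).pvalue)
    raise ConfigError(f"unknown uniformity test {method!r}")


def detect_candidate_chromosomes(
    rearr: RearrangementSet,
    build: GenomeBuild,
    p_threshold: float = UNIFORMITY_P,
    min_breakpoints: int = RATE_MIN_BREAKPOINTS,
    min_translocations: int = MIN_TRANSLOCATIONS,
    uniformity_test: str = "ks",
) -> pd.DataFrame:
    """Per-chromosome candidacy flags for localized complex rearrangement.

    Flags: (A) non-random breakpoint distribution (one-sample test against a
    uniform distribution over the chromosome, p < ``p_threshold``); (B)
    breakpoints/Mb above Q75 + 1.5 IQR of this sample's per-chromosome rates
    (zero-breakpoint chromosomes included at rate 0) with at least
    ``min_breakpoints`` breakpoints; (C) at least ``min_translocations``
    translocations.  A chromosome is a candidate iff any flag fires.
    """
    ends = rearr.breakpoint_ends()
    tra = rearr.events["sv_type"] == "TRA"
    rows = []
    lengths = build.chrom_lengths
    rates = {}
    for chrom in build.chrom_names:
        n = int((ends["chrom"] == chrom).sum())
        rates[chrom] = n / (lengths[chrom] / 1e6)
    rate_vals = np.array(list(rates.values()))
    q75, q25 = np.percentile(rate_vals, [75, 25])
    cutoff = q75 + 1.5 * (q75 - q25)
    for chrom in build.chrom_names:
        pos = ends.loc[ends["chrom"] == chrom, "pos"].to_numpy(dtype=float)
        p = _uniformity_p(pos, lengths[chrom], method=uniformity_test)
        n = len(pos)
        flag_a = p < p_threshold
        flag_b = (rates[chrom] > cutoff) and (n >= min_breakpoints)
        n_tra = int(
            (
                tra
                & ((rearr.events["chrom1"] == chrom) | (rearr.events["chrom2"] == chrom))
            ).sum()
        )
        flag_c = n_tra >= min_translocations
        rows.append(
            (chrom, n, p, flag_a, rates[chrom], flag_b, n_tra, flag_c,
             flag_a or flag_b or flag_c)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "breakpoint_count", "clustered_p", "flag_clustered",
            "rate_per_mb", "flag_rate_outlier", "translocation_count",
            "flag_translocations", "candidate",
        ],
    ).set_index("chrom")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _cn_states_covering(lengths: np.ndarray, totals: np.ndarray, frac: float = 0.8) -> int:
    """Smallest number of distinct CN values covering >= frac of the length."""
    if lengths.sum() == 0:
        return 0
    per_state = {}
    for l, t in zip(lengths, totals):
        per_state[t] = per_state.get(t, 0.0) + l
    covered = 0.0
    target = frac * lengths.sum()
    for i, l in enumerate(sorted(per_state.values(), reverse=True), start=1):
        covered += l
        if covered >= target:
            return i
    return len(per_state)


def classify_complex_chromosome(
    chrom: str,
    profile: SegmentProfile,
    rearr: RearrangementSet,
    flags: pd.Series,
    foldback_span: int = FOLDBACK_SPAN,
) -> ComplexChromosomeCall:
    """Classify one candidate chromosome from CN and breakpoint evidence.

    Evidence: ``telomeric_loss`` — a terminal segment (first or last on the
    chromosome) with total CN below sample ploidy; ``foldback_count`` —
    inversion events whose two ends lie within ``foldback_span``;
    ``cn_switches`` / ``cn_states`` — copy-number oscillation inside the
    breakpoint region; ``het_retention_fraction`` — length fraction of
    higher-CN-state segments that keep a minor allele.  Chromothripsis
    evidence requires >= 10 CN switches between <= 3 states with
    heterozygosity retained; BFB evidence requires telomeric loss plus
    fold-back inversions or an inversion/translocation-dominated event set.
    """
    ev = rearr.events
    touches = (ev["chrom1"] == chrom) | (ev["chrom2"] == chrom)
    chrom_events = ev[touches]
    ends = rearr.breakpoint_ends()
    ends = ends[ends["chrom"] == chrom]

    seg = profile.segments[profile.segments["chrom"] == chrom]
    telomeric_loss = False
    if len(seg):
        first, last = seg.iloc[0], seg.iloc[-1]
        telomeric_loss = bool(
            first["total_cn"] < profile.ploidy or last["total_cn"] < profile.ploidy
        )

    intra = chrom_events["chrom1"] == chrom_events["chrom2"]
    inv = chrom_events["sv_type"] == "INV"
    span = (chrom_events["pos2"] - chrom_events["pos1"]).abs()
    foldback_count = int((inv & intra & (span <= foldback_span)).sum())
    n_ev = len(chrom_events)
    inv_tra = int((inv | (chrom_events["sv_type"] == "TRA")).sum())
    inv_tra_fraction = inv_tra / n_ev if n_ev else 0.0

    if len(ends):
        lo, hi = int(ends["pos"].min()), int(ends["pos"].max())
        region = seg[(seg["end"] >= lo) & (seg["start"] <= hi)]
    else:
        region = seg
    totals = region["total_cn"].to_numpy()
    lengths = (region["end"] - region["start"] + 1).to_numpy(dtype=float)
    minors = region["minor_cn"].to_numpy()
    cn_switches = int((np.diff(totals) != 0).sum()) if len(totals) > 1 else 0
    cn_states = _cn_states_covering(lengths, totals)
    if len(totals):
        floor_state = totals.min()
        high = totals > floor_state if (totals > floor_state).any() else np.ones(
            len(totals), dtype=bool
        )
        hl = lengths[high]
        het_retention = float(hl[minors[high] >= 1].sum() / hl.sum()) if hl.sum() else 0.0
    else:
        het_retention = 0.0

    chromothripsis_ev = (
        cn_switches >= CHROMOTHRIPSIS_MIN_SWITCHES
        and cn_states <= CHROMOTHRIPSIS_MAX_STATES
        and het_retention >= HET_RETENTION_MIN
    )
    bfb_ev = telomeric_loss and (
        foldback_count >= BFB_MIN_FOLDBACKS or inv_tra_fraction >= BFB_INV_TRA_FRACTION
    )
    if bfb_ev and chromothripsis_ev:
        call = "BFB_chromothripsis"
    elif bfb_ev:
        call = "BFB"
    elif chromothripsis_ev:
        call = "chromothripsis"
    else:
        call = "localized_complex"

    return ComplexChromosomeCall(
        sample_id=rearr.sample_id,
        chrom=chrom,
        clustered_p=float(flags["clustered_p"]),
        rate_outlier=bool(flags["flag_rate_outlier"]),
        breakpoint_count=int(flags["breakpoint_count"]),
        translocation_count=int(flags["translocation_count"]),
        candidate=bool(flags["candidate"]),
        telomeric_loss=telomeric_loss,
        foldback_count=foldback_count,
        inv_tra_fraction=float(inv_tra_fraction),
        cn_switches=cn_switches,
        cn_states=cn_states,
        het_retention_fraction=het_retention,
        call=call,
    )


def classify_sample_complexity(
    profile: SegmentProfile,
    rearr: RearrangementSet,
    build: GenomeBuild,
    **candidate_kw,
) -> list:
    """Candidate detection + classification for every chromosome of a sample.

    Non-candidate chromosomes receive call "none" with their flag evidence.
    """
    if len(rearr.events) == 0:
        return []
    flags = detect_candidate_chromosomes(rearr, build, **candidate_kw)
    calls = []
    for chrom, row in flags.iterrows():
        if row["candidate"]:
            calls.append(classify_complex_chromosome(chrom, profile, rearr, row))
        else:
            calls.append(
                ComplexChromosomeCall(
                    sample_id=rearr.sample_id,
                    chrom=chrom,
                    clustered_p=float(row["clustered_p"]),
                    rate_outlier=bool(row["flag_rate_outlier"]),
                    breakpoint_count=int(row["breakpoint_count"]),
                    translocation_count=int(row["translocation_count"]),
                    candidate=False,
                    telomeric_loss=False,
                    foldback_count=0,
                    inv_tra_fraction=0.0,
                    cn_switches=0,
                    cn_states=0,
                    het_retention_fraction=0.0,
                    call="none",
                )
            )
    return calls
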