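"""Mutation, rearrangement and copy-number feature catalogs.

Three category schemes feed signature inference:

* **SBS96** — the pyrimidine-centred trinucleotide single-base-substitution
  scheme (6 substitution classes x 16 flanking contexts).
* **SV32** — rearrangements split by clustered vs non-clustered breakpoints,
  event type (del / dup / inv / trans) and, for intrachromosomal events, five
  size bins: 2 x (3 x 5 + 1) = 32 categories.
* **CN40** — copy-number segments split by zygosity (het / LOH / homozygous
  deletion), total-copy-number class (0-1 deleted, 2 neutral, 3-4 duplicated,
  >4 amplified) and five size bins, keeping only the 40 combinations that
  are genetically possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import (
    ConfigError,
    RearrangementSet,
    SegmentProfile,
    SnvSet,
    ValidationError,
)

__all__ = [
    "FeatureMatrix",
    "SBS96_LABELS",
    "SV32_LABELS",
    "CN40_LABELS",
    "SCHEME_LABELS",
    "build_sbs96",
    "cluster_breakpoints",
    "classify_sv32",
    "classify_cn40",
    "sv32_category",
    "cn40_category",
]

# --- canonical label orders -------------------------------------------------

_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")

#: COSMIC order: substitution class major, 5' then 3' flank alphabetical.
SBS96_LABELS = tuple(
    f"{five}[{sub}]{three}" for sub in _SUBS for five in _BASES for three in _BASES
)

SV_SIZE_BINS = ("1-10kb", "10-100kb", "100kb-1Mb", "1-10Mb", ">10Mb")
_SV_SIZE_EDGES = np.array([10e3, 100e3, 1e6, 10e6])  # upper edges, half-open

SV32_LABELS = tuple(
    f"{clust}:{typ}:{size}"
    for clust in ("non-clustered", "clustered")
    for typ in ("del", "dup", "inv")
    for size in SV_SIZE_BINS
) + tuple(f"{clust}:trans" for clust in ("non-clustered", "clustered"))

CN_SIZE_BINS = ("0-0.01Mb", "0.01-0.1Mb", "0.1-1Mb", "1-10Mb", ">10Mb")
_CN_SIZE_EDGES = np.array([0.01, 0.1, 1.0, 10.0])  # Mb, half-open [low, high)

_CN_CLASSES = ("deleted", "neutral", "duplicated", "amplified")

# Possible (zygosity, cn_class) pairs: het requires total >= 2 and minor >= 1;
# homozygous deletion is total 0 only; LOH (minor 0, total >= 1) spans all four
# classes.  het x 3 + LOH x 4 + homdel x 1 = 8 pairs x 5 size bins = 40.
_CN_PAIRS = (
    [("het", c) for c in ("neutral", "duplicated", "amplified")]
    + [("LOH", c) for c in _CN_CLASSES]
    + [("homdel", "deleted")]
)

CN40_LABELS = tuple(
    f"{zyg}:{cls}:{size}" for zyg, cls in _CN_PAIRS for size in CN_SIZE_BINS
)

SCHEME_LABELS = {"SBS96": SBS96_LABELS, "SV32": SV32_LABELS, "CN40": CN40_LABELS}


@dataclass
class FeatureMatrix:
    """Nonnegative categories x samples count matrix for one scheme."""

    scheme: str
    counts: pd.DataFrame  # index = category labels, columns = sample ids

    def __post_init__(self):
        if self.scheme not in SCHEME_LABELS:
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        labels = SCHEME_LABELS[self.scheme]
        self.counts = self.counts.reindex(list(labels))
        self.counts.index.name = None
        if self.counts.isna().any().any():
            raise ValidationError("feature matrix contains NaN entries")
        self.validate()

    def validate(self):
        vals = self.counts.to_numpy()
        if np.isnan(vals.astype(float)).any():
            raise ValidationError("feature matrix contains NaN entries")
        if (vals < 0).any():
            raise ValidationError("feature matrix contains negative entries")

    @property
    def labels(self) -> tuple:
        return SCHEME_LABELS[self.scheme]

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    def to_array(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    @classmethod
    def from_columns(cls, scheme: str, columns: dict) -> "FeatureMatrix":
        """Build from ``{sample_id: length-matched count vector}``."""
        labels = SCHEME_LABELS[scheme]
        df = pd.DataFrame(
            {s: np.asarray(v) for s, v in columns.items()}, index=list(labels)
        )
        return cls(scheme, df)


# ---------------------------------------------------------------------------
# SBS96
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def sbs96_label(context: str, ref: str, alt: str) -> str | None:
    """Map a trinucleotide context + substitution to its SBS96 label.

    ``context`` is the reference trinucleotide centred on the variant.
    Purine references are reverse-complemented to the pyrimidine strand.
    Returns None when the context contains a non-ACGT base.
    """
    context = context.upper()
    ref, alt = ref.upper(), alt.upper()
    if any(b not in _BASES for b in context) or alt not in _BASES:
        return None
    if context[1] != ref:
        raise ValidationError(f"context {context} does not match ref {ref}")
    if ref in ("A", "G"):
        context = _revcomp(context)
        ref = context[1]
        alt = alt.translate(_COMPLEMENT)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def build_sbs96(snvs: SnvSet, reference) -> tuple:
    """Count SNVs into the 96 trinucleotide classes.

    ``reference`` is a FASTA path or a pyfaidx.Fasta.  Returns
    ``(counts, n_excluded)`` where counts is a length-96 integer vector in
    canonical order; variants whose context contains N are tallied in
    ``n_excluded`` instead of a class.
    """
    import pyfaidx

    fasta = reference if isinstance(reference, pyfaidx.Fasta) else pyfaidx.Fasta(
        str(reference), sequence_always_upper=True
    )
    keys = {k.replace("chr", ""): k for k in fasta.keys()}
    index = {lab: i for i, lab in enumerate(SBS96_LABELS)}
    counts = np.zeros(96, dtype=np.int64)
    excluded = 0
    for r in snvs.variants.itertuples():
        key = keys.get(r.chrom, r.chrom)
        ctx = str(fasta[key][r.pos - 2 : r.pos + 1]).upper()
        if len(ctx) != 3:
            excluded += 1
            continue
        lab = sbs96_label(ctx, r.ref, r.alt)
        if lab is None:
            excluded += 1
        else:
            counts[index[lab]] += 1
    return counts, excluded


# ---------------------------------------------------------------------------
# SV32
# ---------------------------------------------------------------------------


def cluster_breakpoints(
    rearr: RearrangementSet, distance_d: float = 1e6, min_cluster_size: int = 10
) -> np.ndarray:
    """Flag events whose breakpoints fall in a breakpoint cluster.

    Individual breakpoint ends are single-linkage clustered along each
    chromosome with merge distance ``distance_d``; an event is clustered iff
    either of its ends belongs to a cluster of >= ``min_cluster_size`` ends.
    Returns a boolean array aligned with ``rearr.events``.
    """
    if distance_d < 0:
        raise ConfigError("clustering distance must be >= 0")
    ends = rearr.breakpoint_ends()
    clustered = np.zeros(len(rearr.events), dtype=bool)
    for _, grp in ends.groupby("chrom", sort=False):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy()
        if len(pos) == 0:
            continue
        # single linkage on a line: break where the gap exceeds d
        breaks = np.flatnonzero(np.diff(pos) > distance_d)
        cluster_id = np.zeros(len(pos), dtype=int)
        cluster_id[1:] = np.cumsum(np.diff(pos) > distance_d)
        sizes = np.bincount(cluster_id)
        big = sizes[cluster_id] >= min_cluster_size
        clustered[grp["event_index"].to_numpy()[big]] = True
    return clustered


def _sv_size_bin(size: float) -> str:
    """Half-open [low, high) bins; events below 10 kb share the first bin."""
    return SV_SIZE_BINS[int(np.searchsorted(_SV_SIZE_EDGES, size, side="right"))]


def sv32_category(sv_type: str, size: float | None, clustered: bool) -> str:
    clust = "clustered" if clustered else "non-clustered"
    if sv_type == "TRA":
        return f"{clust}:trans"
    typ = {"DEL": "del", "DUP": "dup", "INV": "inv"}[sv_type]
    return f"{clust}:{typ}:{_sv_size_bin(size)}"


def classify_sv32(
    rearr: RearrangementSet, clustered_flags: np.ndarray | None = None, **cluster_kw
) -> np.ndarray:
    """Count events into the 32 rearrangement categories (canonical order)."""
    if clustered_flags is None:
        clustered_flags = cluster_breakpoints(rearr, **cluster_kw)
    index = {lab: i for i, lab in enumerate(SV32_LABELS)}
    counts = np.zeros(32, dtype=np.int64)
    sizes = rearr.size.to_numpy()
    for i, r in enumerate(rearr.events.itertuples()):
        counts[index[sv32_category(r.sv_type, sizes[i], bool(clustered_flags[i]))]] += 1
    return counts


# ---------------------------------------------------------------------------
# CN40
# ---------------------------------------------------------------------------


def _cn_size_bin(size_mb: float) -> str:
    return CN_SIZE_BINS[int(np.searchsorted(_CN_SIZE_EDGES, size_mb, side="right"))]


def cn40_category(total_cn: int, minor_cn: int, length_bp: int) -> str:
    if total_cn == 0:
        zyg, cls = "homdel", "deleted"
    else:
        zyg = "LOH" if minor_cn == 0 else "het"
        if total_cn <= 1:
            cls = "deleted"
        elif total_cn == 2:
            cls = "neutral"
        elif total_cn <= 4:
            cls = "duplicated"
        else:
            cls = "amplified"
    return f"{zyg}:{cls}:{_cn_size_bin(length_bp / 1e6)}"


def classify_cn40(profile: SegmentProfile) -> np.ndarray:
    """Count segments into the 40 copy-number categories (canonical order)."""
    index = {lab: i for i, lab in enumerate(CN40_LABELS)}
    counts = np.zeros(40, dtype=np.int64)
    for r in profile.segments.itertuples():
        counts[index[cn40_category(r.total_cn, r.minor_cn, r.end - r.start + 1)]] += 1
    return counts
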