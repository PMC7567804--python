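"""Domain types, coordinate conventions and file I/O for the pipeline.

All in-memory coordinates are 1-based inclusive (the convention of VCF and
of allele-specific copy-number callers).  BED/BEDPE files are 0-based
half-open on disk and are converted at the boundary.  Chromosome names are
normalized by stripping a leading ``chr`` prefix.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "InsufficientDataError",
    "ConfigError",
    "Arm",
    "GenomeBuild",
    "SegmentProfile",
    "RearrangementSet",
    "SnvSet",
    "IntervalTrack",
    "AUTOSOMES",
    "ACROCENTRIC",
    "normalize_chrom",
    "load_genome_build",
    "grch37_build",
    "mini_build",
    "read_segments",
    "write_segments",
    "read_bedpe",
    "write_bedpe",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "write_fasta",
    "read_sample",
    "split_at_arms",
    "read_feature_matrix",
    "write_feature_matrix",
]


class FormatError(ValueError):
    """A file does not parse under the expected dialect."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


class InsufficientDataError(ValueError):
    """Not enough data to compute the requested quantity."""


class ConfigError(ValueError):
    """Invalid parameter value."""


AUTOSOMES = tuple(str(i) for i in range(1, 23))
#: Acrocentric chromosomes whose short (p) arms are not counted for aneuploidy.
ACROCENTRIC = frozenset({"13", "14", "15", "21", "22"})

SV_TYPES = ("DEL", "DUP", "INV", "TRA")


def normalize_chrom(name) -> str:
    name = str(name)
    return name[3:] if name.lower().startswith("chr") else name


# ---------------------------------------------------------------------------
# Genome build
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Arm:
    """A chromosome arm interval (1-based inclusive).

    ``counted`` is True for autosomal arms that enter the aneuploidy score,
    i.e. all autosomal arms except the short arms of the acrocentric
    chromosomes 13, 14, 15, 21 and 22.
    """

    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int
    counted: bool

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths and centromere positions for one genome build.

    Arms are derived as p = [1, cen_start] and q = [cen_end, length],
    1-based inclusive; the interior of the centromere belongs to neither arm.
    """

    name: str
    chroms: tuple  # of (chrom, length, cen_start, cen_end)

    def __post_init__(self):
        seen = set()
        for chrom, length, cs, ce in self.chroms:
            if chrom in seen:
                raise ValidationError(f"duplicate chromosome {chrom!r}")
            seen.add(chrom)
            if length <= 0:
                raise ValidationError(f"chromosome {chrom}: length must be > 0")
            if not (1 <= cs <= ce <= length):
                raise ValidationError(
                    f"chromosome {chrom}: centromere [{cs}, {ce}] outside [1, {length}]"
                )

    @property
    def chrom_names(self) -> tuple:
        return tuple(c[0] for c in self.chroms)

    @property
    def chrom_lengths(self) -> dict:
        return {c[0]: c[1] for c in self.chroms}

    def centromere(self, chrom: str) -> tuple:
        for c, _, cs, ce in self.chroms:
            if c == chrom:
                return cs, ce
        raise KeyError(chrom)

    def arms(self, chrom: str | None = None) -> list:
        """All arms, or the two arms of one chromosome."""
        out = []
        for c, length, cs, ce in self.chroms:
            if chrom is not None and c != chrom:
                continue
            autosomal = c in AUTOSOMES
            out.append(Arm(c, "p", 1, cs, autosomal and c not in ACROCENTRIC))
            out.append(Arm(c, "q", ce, length, autosomal))
        return out

    def counted_arms(self) -> list:
        """Autosomal arms counted by the aneuploidy score (39 on GRCh37)."""
        return [a for a in self.arms() if a.counted]

    def autosome_length(self) -> int:
        return sum(l for c, l, _, _ in self.chroms if c in AUTOSOMES)

    def scaled(self, factor: float, name: str | None = None) -> "GenomeBuild":
        """A build with all coordinates scaled by ``factor`` (for simulation)."""
        rows = tuple(
            (c, max(int(l * factor), 10), max(int(cs * factor), 2), max(int(ce * factor), 3))
            for c, l, cs, ce in self.chroms
        )
        return GenomeBuild(name or f"{self.name}-x{factor:g}", rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.chroms), columns=["chrom", "length", "cen_start", "cen_end"]
        )


def load_genome_build(path, name: str | None = None) -> GenomeBuild:
    """Load a chromosome/centromere table (TSV: chrom, length, cen_start, cen_end)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "length", "cen_start", "cen_end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"genome build table missing columns: {sorted(missing)}")
    rows = tuple(
        (normalize_chrom(r.chrom), int(r.length), int(r.cen_start), int(r.cen_end))
        for r in df.itertuples()
    )
    return GenomeBuild(name or Path(str(path)).stem, rows)


def _packaged(fname: str) -> Path:
    return resources.files("tumorcomplexity").joinpath("data", fname)


def grch37_build() -> GenomeBuild:
    """The packaged GRCh37 chromosome-arm table."""
    return load_genome_build(_packaged("grch37_arms.tsv"), name="GRCh37")


def mini_build() -> GenomeBuild:
    """The packaged mini genome: GRCh37 scaled 1:10 (~310 Mb), for fast runs."""
    return load_genome_build(_packaged("mini_arms.tsv"), name="mini")


# ---------------------------------------------------------------------------
# Per-sample data containers
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = ["chrom", "start", "end", "total_cn", "minor_cn"]


@dataclass
class SegmentProfile:
    """Allele-specific copy-number segments for one sample.

    ``minor_cn`` is the copy number of the less frequent allele, so the major
    copy number (the most frequent allele) is ``total_cn - minor_cn``.
    """

    sample_id: str
    segments: pd.DataFrame
    ploidy: float
    purity: float

    def __post_init__(self):
        seg = pd.DataFrame(self.segments, columns=SEGMENT_COLUMNS).copy()
        seg["chrom"] = seg["chrom"].map(normalize_chrom)
        for c in ("start", "end", "total_cn", "minor_cn"):
            seg[c] = seg[c].astype(np.int64)
        seg = seg.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        if (seg["end"] < seg["start"]).any():
            bad = seg[seg["end"] < seg["start"]].iloc[0]
            raise ValidationError(f"segment end < start at {bad.chrom}:{bad.start}")
        if (seg["total_cn"] < 0).any() or (seg["minor_cn"] < 0).any():
            raise ValidationError("copy numbers must be >= 0")
        if (seg["minor_cn"] > seg["total_cn"] - seg["minor_cn"]).any():
            bad = seg[seg["minor_cn"] > seg["total_cn"] - seg["minor_cn"]].iloc[0]
            raise ValidationError(
                f"minor_cn > major_cn at {bad.chrom}:{bad.start} "
                f"(total {bad.total_cn}, minor {bad.minor_cn})"
            )
        for chrom, grp in seg.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            overlap = starts[1:] <= ends[:-1]
            if overlap.any():
                i = int(np.flatnonzero(overlap)[0])
                raise ValidationError(
                    f"overlapping segments on {chrom}: "
                    f"[{starts[i]}, {ends[i]}] and [{starts[i + 1]}, {ends[i + 1]}]"
                )
        if not 0.0 <= self.purity <= 1.0:
            raise ValidationError("purity must be in [0, 1]")
        self.segments = seg

    @property
    def major_cn(self) -> pd.Series:
        return self.segments["total_cn"] - self.segments["minor_cn"]

    @property
    def lengths(self) -> pd.Series:
        return self.segments["end"] - self.segments["start"] + 1

    def autosomal(self) -> pd.DataFrame:
        return self.segments[self.segments["chrom"].isin(AUTOSOMES)]


BEDPE_COLUMNS = [
    "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2", "sv_type",
]


@dataclass
class RearrangementSet:
    """Typed, oriented structural-rearrangement breakpoint pairs for one sample."""

    sample_id: str
    events: pd.DataFrame

    def __post_init__(self):
        ev = pd.DataFrame(self.events, columns=BEDPE_COLUMNS).copy()
        ev["chrom1"] = ev["chrom1"].map(normalize_chrom)
        ev["chrom2"] = ev["chrom2"].map(normalize_chrom)
        ev["pos1"] = ev["pos1"].astype(np.int64)
        ev["pos2"] = ev["pos2"].astype(np.int64)
        bad_type = ~ev["sv_type"].isin(SV_TYPES)
        if bad_type.any():
            raise FormatError(
                f"unknown sv_type {ev.loc[bad_type, 'sv_type'].iloc[0]!r}"
            )
        if not ev["strand1"].isin(["+", "-"]).all() or not ev["strand2"].isin(["+", "-"]).all():
            raise ValidationError("strands must be '+' or '-'")
        intra = ev["chrom1"] == ev["chrom2"]
        if (intra & (ev["sv_type"] == "TRA")).any():
            raise ValidationError("TRA event with chrom1 == chrom2")
        if (~intra & (ev["sv_type"] != "TRA")).any():
            raise ValidationError("interchromosomal event typed as non-TRA")
        # canonical orientation: intrachromosomal events with pos1 <= pos2
        flip = intra & (ev["pos2"] < ev["pos1"])
        if flip.any():
            f = ev.loc[flip]
            ev.loc[flip, ["pos1", "pos2"]] = f[["pos2", "pos1"]].to_numpy()
            ev.loc[flip, ["strand1", "strand2"]] = f[["strand2", "strand1"]].to_numpy()
        if (intra & (ev["pos2"] - ev["pos1"] < 1)).any():
            raise ValidationError("intrachromosomal event with size < 1 bp")
        ev = ev.sort_values(["chrom1", "pos1", "chrom2", "pos2"], kind="stable")
        self.events = ev.reset_index(drop=True)

    @property
    def size(self) -> pd.Series:
        """Event size |pos2 - pos1| for intrachromosomal events, NA for TRA."""
        intra = self.events["chrom1"] == self.events["chrom2"]
        s = (self.events["pos2"] - self.events["pos1"]).abs().astype("float")
        s[~intra] = np.nan
        return s

    def breakpoint_ends(self) -> pd.DataFrame:
        """One row per breakpoint end: columns chrom, pos, event_index."""
        ev = self.events
        a = pd.DataFrame(
            {"chrom": ev["chrom1"], "pos": ev["pos1"], "event_index": ev.index}
        )
        b = pd.DataFrame(
            {"chrom": ev["chrom2"], "pos": ev["pos2"], "event_index": ev.index}
        )
        return pd.concat([a, b], ignore_index=True)


@dataclass
class SnvSet:
    """Somatic single-nucleotide variants for one sample (1-based positions)."""

    sample_id: str
    variants: pd.DataFrame

    def __post_init__(self):
        v = pd.DataFrame(self.variants, columns=["chrom", "pos", "ref", "alt"]).copy()
        v["chrom"] = v["chrom"].map(normalize_chrom)
        v["pos"] = v["pos"].astype(np.int64)
        v["ref"] = v["ref"].astype(str).str.upper()
        v["alt"] = v["alt"].astype(str).str.upper()
        if (v["ref"].str.len() != 1).any() or (v["alt"].str.len() != 1).any():
            raise ValidationError("SnvSet holds single-base substitutions only")
        if (v["ref"] == v["alt"]).any():
            raise ValidationError("ref == alt")
        v = v.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        self.variants = v


@dataclass
class IntervalTrack:
    """Named genomic intervals (super-enhancers, genes); 1-based inclusive."""

    name: str
    intervals: pd.DataFrame  # chrom, start, end, label

    def __post_init__(self):
        iv = pd.DataFrame(
            self.intervals, columns=["chrom", "start", "end", "label"]
        ).copy()
        iv["chrom"] = iv["chrom"].map(normalize_chrom)
        iv["start"] = iv["start"].astype(np.int64)
        iv["end"] = iv["end"].astype(np.int64)
        if (iv["end"] < iv["start"]).any():
            raise ValidationError(f"track {self.name}: interval end < start")
        iv = iv.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self.intervals = iv


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_segments(path) -> SegmentProfile:
    """Read a segment TSV with ``#ploidy=`` / ``#purity=`` header lines."""
    ploidy = purity = None
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#ploidy="):
                ploidy = float(line.strip().split("=", 1)[1])
            elif line.startswith("#purity="):
                purity = float(line.strip().split("=", 1)[1])
            elif line.startswith("#"):
                continue
            else:
                lines.append(line)
    if ploidy is None or purity is None:
        raise FormatError(f"{path}: missing #ploidy= or #purity= header")
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", dtype={"chrom": str})
    required = {"sample", "chrom", "start", "end", "total_cn", "minor_cn"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    samples = df["sample"].unique()
    if len(samples) > 1:
        raise FormatError(f"{path}: multiple samples in one segment file")
    sample_id = str(samples[0]) if len(samples) else Path(str(path)).stem
    return SegmentProfile(sample_id, df[SEGMENT_COLUMNS], ploidy, purity)


def write_segments(profile: SegmentProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#ploidy={profile.ploidy:.6g}\n#purity={profile.purity:.6g}\n")
        df = profile.segments.copy()
        df.insert(0, "sample", profile.sample_id)
        df.to_csv(fh, sep="\t", index=False)


def read_bedpe(path, sample_id: str | None = None) -> RearrangementSet:
    """Read a 10-column BEDPE with ``sv_type`` in column 11.

    BEDPE is 0-based half-open on disk; each breakpoint position is taken as
    the interval start converted to 1-based (start + 1).
    """
    names = [
        "chrom1", "start1", "end1", "chrom2", "start2", "end2",
        "name", "score", "strand1", "strand2", "sv_type",
    ]
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=names,
            dtype={"chrom1": str, "chrom2": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=names)
    if len(df) and df["sv_type"].isna().any():
        raise FormatError(f"{path}: missing sv_type column (column 11)")
    ev = pd.DataFrame(
        {
            "chrom1": df["chrom1"],
            "pos1": df["start1"].astype("int64", errors="ignore") + 1 if len(df) else [],
            "strand1": df["strand1"],
            "chrom2": df["chrom2"],
            "pos2": df["start2"].astype("int64", errors="ignore") + 1 if len(df) else [],
            "strand2": df["strand2"],
            "sv_type": df["sv_type"],
        }
    )
    sid = sample_id or Path(str(path)).stem
    return RearrangementSet(sid, ev)


def write_bedpe(rearr: RearrangementSet, path) -> None:
    ev = rearr.events
    out = pd.DataFrame(
        {
            "chrom1": ev["chrom1"],
            "start1": ev["pos1"] - 1,
            "end1": ev["pos1"],
            "chrom2": ev["chrom2"],
            "start2": ev["pos2"] - 1,
            "end2": ev["pos2"],
            "name": [f"{rearr.sample_id}_sv{i}" for i in range(len(ev))],
            "score": ".",
            "strand1": ev["strand1"],
            "strand2": ev["strand2"],
            "sv_type": ev["sv_type"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic variant">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def read_vcf(path, sample_id: str | None = None) -> SnvSet:
    """Read somatic SNVs from a VCF 4.2 file; non-SNV records are skipped."""
    import cyvcf2

    rows = []
    for rec in cyvcf2.VCF(str(path)):
        if len(rec.REF) != 1 or len(rec.ALT) != 1 or len(rec.ALT[0]) != 1:
            continue  # indels / MNVs / multi-allelics are out of scope here
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    sid = sample_id or Path(str(path)).stem
    return SnvSet(sid, pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]))


def write_vcf(snvs: SnvSet, path, build: GenomeBuild | None = None) -> None:
    header = _VCF_HEADER
    chroms = build.chrom_names if build is not None else snvs.variants["chrom"].unique()
    contigs = "".join(f"##contig=<ID={c}>\n" for c in chroms)
    head, tail = header.rsplit("#CHROM", 1)
    with open(path, "w") as fh:
        fh.write(head + contigs + "#CHROM" + tail)
        for r in snvs.variants.itertuples():
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\tSOMATIC\n")


def read_bed(path, name: str | None = None) -> IntervalTrack:
    """Read a BED4 track (0-based half-open on disk -> 1-based inclusive)."""
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "label"], dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "label"])
    if len(df):
        df["start"] = df["start"].astype(np.int64) + 1
    return IntervalTrack(name or Path(str(path)).stem, df)


def write_bed(track: IntervalTrack, path) -> None:
    out = track.intervals.copy()
    out["start"] = out["start"] - 1
    out.to_csv(path, sep="\t", index=False, header=False)


def write_fasta(sequences: dict, path, width: int = 80) -> None:
    """Write ``{name: sequence}`` to a FASTA file."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def split_at_arms(profile: SegmentProfile, build: GenomeBuild) -> SegmentProfile:
    """Split segments that cross arm boundaries (the centromere).

    A segment overlapping the centromere is cut into a p-arm part
    [start, cen_start], an intra-centromeric part and a q-arm part
    [cen_end, end]; empty parts are dropped.  Copy numbers are inherited.
    After splitting, no segment spans both arm intervals, which makes
    arm-level length sums well defined.
    """
    cens = {c: build.centromere(c) for c in build.chrom_names}
    rows = []
    for r in profile.segments.itertuples(index=False):
        if r.chrom not in cens:
            rows.append(tuple(r))
            continue
        cs, ce = cens[r.chrom]
        cuts = [r.start - 1, r.end]
        for b in (cs, ce - 1):  # boundaries after cen_start and before cen_end
            if r.start - 1 < b < r.end:
                cuts.append(b)
        cuts = sorted(set(cuts))
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            rows.append((r.chrom, lo + 1, hi, r.total_cn, r.minor_cn))
    seg = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return SegmentProfile(profile.sample_id, seg, profile.ploidy, profile.purity)


def read_sample(
    segments_path,
    bedpe_path,
    vcf_path,
    build: GenomeBuild | None = None,
    sample_id: str | None = None,
):
    """Read one sample's segment, rearrangement and SNV files.

    If a genome build is given, segments are split at arm boundaries.
    """
    profile = read_segments(segments_path)
    sid = sample_id or profile.sample_id
    if build is not None:
        profile = split_at_arms(profile, build)
    rearr = read_bedpe(bedpe_path, sample_id=sid)
    snvs = read_vcf(vcf_path, sample_id=sid)
    return profile, rearr, snvs


def write_feature_matrix(matrix, path) -> None:
    """Write a FeatureMatrix as TSV (categories as rows, canonical order)."""
    from .feature_catalogs import FeatureMatrix  # local import avoids a cycle

    if not isinstance(matrix, FeatureMatrix):
        raise TypeError("expected a FeatureMatrix")
    matrix.validate()
    matrix.counts.to_csv(path, sep="\t", index_label="category")


def read_feature_matrix(path):
    from .feature_catalogs import FeatureMatrix, SCHEME_LABELS

    df = pd.read_csv(path, sep="\t", index_col="category")
    for scheme, labels in SCHEME_LABELS.items():
        if list(df.index) == list(labels):
            return FeatureMatrix(scheme, df)
    raise FormatError("category rows do not match any known scheme")
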