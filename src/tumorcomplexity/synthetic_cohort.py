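"""Synthetic tumor-cohort generator with truth labels.

Generates per-sample allele-specific copy-number profiles, rearrangement
breakpoints, somatic SNVs and a random reference sequence, with planted
whole-genome doubling, arm-level gains/losses, focal amplifications and
homozygous deletions, chromothripsis and breakage-fusion-bridge
chromosomes, kataegis loci and SBS-signature mixtures.  Every planted
structure is recorded in a :class:`TruthLabels` object so downstream
callers can be scored against ground truth.

Each sample draws from an independent random stream derived from
``(master seed, sample index)``, so cohorts are reproducible regardless of
generation order.  The default genome is the packaged mini genome (GRCh37
scaled 1:10, ~310 Mb) which keeps full-cohort runs fast; any
:class:`GenomeBuild` can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    AUTOSOMES,
    ConfigError,
    GenomeBuild,
    RearrangementSet,
    SegmentProfile,
    SnvSet,
    mini_build,
    write_bedpe,
    write_fasta,
    write_segments,
    write_vcf,
)
from .feature_catalogs import (
    FeatureMatrix,
    SBS96_LABELS,
    SV32_LABELS,
    sv32_category,
)

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "simulate_reference",
    "simulate_sample",
    "simulate_cohort",
    "simulate_catalog",
    "synthetic_sbs_signatures",
    "apobec_like_signature",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = dict(zip("ACGT", "TGCA"))

_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")


def synthetic_sbs_signatures(k: int = 3, seed: int = 20210, concentration: float = 0.05) -> np.ndarray:
    """K synthetic, sparse, mutually distinct SBS96 signatures (96 x k).

    These are synthetic stand-ins drawn from a sparse Dirichlet — they are
    not COSMIC signatures; they exist so that planted mixtures have a known
    generating basis.
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):
        W = rng.dirichlet(np.full(96, concentration), size=k).T
        gram = (W / np.linalg.norm(W, axis=0)).T @ (W / np.linalg.norm(W, axis=0))
        np.fill_diagonal(gram, 0.0)
        if gram.max() < 0.3:
            return W
    raise RuntimeError("could not draw distinct signatures")


def apobec_like_signature() -> np.ndarray:
    """A TpC-focused C>T / C>G signature of the kind enriched in kataegis."""
    w = np.zeros(96)
    for i, lab in enumerate(SBS96_LABELS):
        if lab.startswith("T[C>T]"):
            w[i] = 0.7 / 4
        elif lab.startswith("T[C>G]"):
            w[i] = 0.3 / 4
    return w


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Rates are per sample unless stated otherwise.  ``background_sv_rate``
    is breakpoint *ends* per megabase (two ends per event).  Planted
    chromothripsis chromosomes carry ``chromothripsis_breakpoints``
    clustered breakpoint ends with copy number oscillating between two
    states, heterozygosity retained on the higher state; planted BFB
    chromosomes carry a telomere-adjacent loss plus ``bfb_foldbacks``
    fold-back-like inversions.  Kataegis loci have at least 6 mutations
    with exponentially distributed spacing (mean ``kataegis_spacing_mean``
    bp) in TpC context with C>T / C>G alternates.
    """

    seed: int = 0
    n_samples: int = 10
    genome: GenomeBuild | None = None
    wgd_probability: float = 0.5
    arm_event_rate: float = 4.0
    focal_amp_rate: float = 2.0
    focal_del_rate: float = 2.0
    background_sv_rate: float = 0.18
    n_chromothripsis: int = 1
    n_bfb: int = 1
    chromothripsis_breakpoints: int = 44
    chromothripsis_window: float | None = None
    bfb_foldbacks: int = 8
    kataegis_loci: int = 2
    kataegis_cluster_size: int = 8
    kataegis_spacing_mean: float = 300.0
    snv_count: int = 650  # ~2.1 SNVs/Mb on the 310-Mb mini genome
    sbs_signatures: np.ndarray | None = None  # 96 x K
    exposures: np.ndarray | None = None  # (K,) or (n_samples, K)
    sv_category_exposures: np.ndarray | None = None  # (32,)
    cn_category_targets: np.ndarray | None = None  # (40,), catalog-level sims

    def __post_init__(self):
        if self.genome is None:
            self.genome = mini_build()
        if not 0.0 <= self.wgd_probability <= 1.0:
            raise ConfigError("wgd_probability must be in [0, 1]")
        if self.sbs_signatures is None:
            self.sbs_signatures = synthetic_sbs_signatures(3)
        self.sbs_signatures = np.asarray(self.sbs_signatures, dtype=float)
        k = self.sbs_signatures.shape[1]
        if self.exposures is None:
            self.exposures = np.full(k, 1.0 / k)
        self.exposures = np.asarray(self.exposures, dtype=float)
        exp2 = np.atleast_2d(self.exposures)
        if exp2.shape[1] != k:
            raise ConfigError("exposures length does not match signature count")
        if (exp2 < 0).any() or not np.allclose(exp2.sum(axis=1), 1.0, atol=1e-8):
            raise ConfigError("exposure vectors must be nonnegative and sum to 1")
        if self.sv_category_exposures is None:
            self.sv_category_exposures = np.full(32, 1.0 / 32)
        self.sv_category_exposures = np.asarray(self.sv_category_exposures, dtype=float)
        if (self.sv_category_exposures < 0).any() or not np.isclose(
            self.sv_category_exposures.sum(), 1.0, atol=1e-8
        ):
            raise ConfigError("sv_category_exposures must be nonnegative and sum to 1")

    def sample_exposures(self, sample_index: int) -> np.ndarray:
        exp2 = np.atleast_2d(self.exposures)
        return exp2[0] if exp2.shape[0] == 1 else exp2[sample_index]


@dataclass
class TruthLabels:
    """Planted ground truth for one synthetic sample."""

    sample_id: str
    wgd: bool
    wgd_fraction: float
    ploidy: float
    arm_calls: dict  # arm name -> gain | loss | neutral
    complex_chroms: dict  # chrom -> BFB | chromothripsis
    kataegis_loci: list  # (chrom, start, end, n_mutations, mean_imd)
    exposures: np.ndarray
    sv32_counts: np.ndarray


# ---------------------------------------------------------------------------
# Reference sequence
# ---------------------------------------------------------------------------


def simulate_reference(config: SimulationConfig) -> dict:
    """Random reference sequence per chromosome, deterministic in the seed.

    Returns ``{chrom: bytes}`` of uppercase A/C/G/T.
    """
    rng = np.random.default_rng([config.seed, 0xFA57A])
    out = {}
    for chrom, length in config.genome.chrom_lengths.items():
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        out[chrom] = _BASE_BYTES[codes].tobytes()
    return out


# ---------------------------------------------------------------------------
# Copy-number scaffolding
# ---------------------------------------------------------------------------


class _ChromSegments:
    """Mutable integer-CN segment list for one chromosome."""

    def __init__(self, length: int, total: int, minor: int):
        self.segs = [(1, length, total, minor)]

    def apply(self, start: int, end: int, fn) -> None:
        out = []
        for s, e, t, m in self.segs:
            if e < start or s > end:
                out.append((s, e, t, m))
                continue
            if s < start:
                out.append((s, start - 1, t, m))
            nt, nm = fn(t, m)
            nm = min(nm, nt // 2)
            out.append((max(s, start), min(e, end), nt, max(nm, 0)))
            if e > end:
                out.append((end + 1, e, t, m))
        self.segs = sorted(out)


def _choose_sized_chrom(rng, lengths: dict, exclude: set, min_len: float) -> str | None:
    ok = [c for c, l in lengths.items() if c not in exclude and l >= min_len]
    if not ok:
        return None
    w = np.array([lengths[c] for c in ok], dtype=float)
    return ok[rng.choice(len(ok), p=w / w.sum())]


_SV_BIN_RANGES = {
    "1-10kb": (1e3, 10e3),
    "10-100kb": (10e3, 100e3),
    "100kb-1Mb": (100e3, 1e6),
    "1-10Mb": (1e6, 10e6),
    ">10Mb": (10e6, 30e6),
}


# ---------------------------------------------------------------------------
# Per-sample simulation
# ---------------------------------------------------------------------------


def simulate_sample(
    config: SimulationConfig,
    sample_index: int,
    reference: dict | None = None,
) -> tuple:
    """Simulate one sample: (profile, rearrangements, snvs, reference, truth).

    Deterministic given ``(config.seed, sample_index)``; the reference is
    deterministic given ``config.seed`` alone and may be passed in to avoid
    regenerating it for each sample of a cohort.
    """
    if reference is None:
        reference = simulate_reference(config)
    rng = np.random.default_rng([config.seed, sample_index])
    build = config.genome
    lengths = build.chrom_lengths
    sid = f"S{sample_index:03d}"

    wgd = bool(rng.random() < config.wgd_probability)
    base_total, base_minor = (4, 2) if wgd else (2, 1)
    ploidy = float(base_total)
    purity = float(rng.uniform(0.5, 0.95))

    chrom_segs = {
        c: _ChromSegments(lengths[c], base_total, base_minor) for c in build.chrom_names
    }

    # -- complex chromosomes first so other events can avoid them
    big_autosomes = sorted(
        (c for c in AUTOSOMES if c in lengths), key=lambda c: -lengths[c]
    )[:12]
    order = list(big_autosomes)
    rng.shuffle(order)
    n_complex = config.n_chromothripsis + config.n_bfb
    complex_chroms = order[:n_complex]
    ct_chroms = complex_chroms[: config.n_chromothripsis]
    bfb_chroms = complex_chroms[config.n_chromothripsis : n_complex]
    complex_set = set(complex_chroms)
    truth_complex = {}

    events = []  # rows of the rearrangement table
    truth_cats = []  # canonical SV32 truth category per event

    def _add_event(c1, p1, s1, c2, p2, s2, typ, clustered):
        events.append((c1, int(p1), s1, c2, int(p2), s2, typ))
        size = abs(int(p2) - int(p1)) if c1 == c2 else None
        truth_cats.append(sv32_category(typ, size, clustered))

    # chromothripsis: shatter a window, alternate two CN states (high state
    # keeps a minor allele), clustered breakpoints at the segment boundaries
    for chrom in ct_chroms:
        L = lengths[chrom]
        cs, ce = build.centromere(chrom)
        window = config.chromothripsis_window or min(30e6, 0.6 * (L - ce))
        window = min(window, 0.8 * (L - ce))
        w0 = int(rng.uniform(ce, L - window))
        n_bp = config.chromothripsis_breakpoints
        cuts = np.array([], dtype=np.int64)
        while len(cuts) < n_bp:  # draw until n_bp distinct cut points
            extra = rng.integers(w0 + 10, w0 + int(window) - 10, size=n_bp)
            cuts = np.unique(np.concatenate([cuts, extra]))[:n_bp]
        cuts = np.sort(cuts)
        lo_t, lo_m = base_total - 1, max(base_minor - 1, 0)
        bounds = [w0] + list(cuts) + [w0 + int(window)]
        for i in range(1, len(bounds) - 1, 2):  # alternate pieces drop a copy
            chrom_segs[chrom].apply(
                int(bounds[i]) + 1, int(bounds[i + 1]), lambda t, m: (lo_t, lo_m)
            )
        for i in range(0, n_bp - 1, 2):
            typ = ("DEL", "DUP", "INV")[rng.integers(3)]
            s1, s2 = rng.choice(["+", "-"], size=2)
            _add_event(chrom, cuts[i], s1, chrom, cuts[i + 1], s2, typ, True)
        truth_complex[chrom] = "chromothripsis"

    # BFB: telomere-adjacent loss on the q arm plus fold-back inversions
    for chrom in bfb_chroms:
        L = lengths[chrom]
        cs, ce = build.centromere(chrom)
        q_len = L - ce
        loss_len = int(rng.uniform(0.15, 0.3) * q_len)
        loss_start = L - loss_len + 1
        chrom_segs[chrom].apply(
            loss_start, L, lambda t, m: (t - 1, max(m - 1, 0))
        )
        span_region = max(int(0.15 * q_len), 50_000)
        for _ in range(config.bfb_foldbacks):
            span = int(rng.integers(1_000, 20_000))
            p1 = int(rng.integers(max(loss_start - span_region, ce + 1), loss_start))
            _add_event(chrom, p1, "+", chrom, p1 + span, "+", "INV", True)
        truth_complex[chrom] = "BFB"

    # arm-level gains and losses on non-complex chromosomes
    arms = [a for a in build.counted_arms() if a.chrom not in complex_set]
    n_arm = min(int(rng.poisson(config.arm_event_rate)), len(arms))
    chosen = rng.choice(len(arms), size=n_arm, replace=False) if n_arm else []
    truth_arms = {
        a.name: "neutral" for a in build.counted_arms() if a.chrom not in complex_set
    }
    for ai in chosen:
        arm = arms[int(ai)]
        if rng.random() < 0.5:
            chrom_segs[arm.chrom].apply(arm.start, arm.end, lambda t, m: (t + 1, m))
            truth_arms[arm.name] = "gain"
        else:
            chrom_segs[arm.chrom].apply(
                arm.start, arm.end, lambda t, m: (max(t - 1, 0), max(m - 1, 0))
            )
            truth_arms[arm.name] = "loss"

    # focal amplifications and homozygous deletions
    for n_ev, setter, size_rng in (
        (rng.poisson(config.focal_amp_rate), lambda t, m: (8, 1), (2e5, 2e6)),
        (rng.poisson(config.focal_del_rate), lambda t, m: (0, 0), (5e4, 5e5)),
    ):
        for _ in range(int(n_ev)):
            size = int(np.exp(rng.uniform(np.log(size_rng[0]), np.log(size_rng[1]))))
            chrom = _choose_sized_chrom(
                rng, {c: lengths[c] for c in AUTOSOMES if c in lengths},
                complex_set, size * 3,
            )
            if chrom is None:
                continue
            start = int(rng.integers(1, lengths[chrom] - size))
            chrom_segs[chrom].apply(start, start + size - 1, setter)

    # background (non-clustered) rearrangements
    genome_mb = sum(lengths.values()) / 1e6
    n_bg_events = int(rng.poisson(config.background_sv_rate * genome_mb)) // 2
    nc_mask = np.array([lab.startswith("non-clustered") for lab in SV32_LABELS])
    p_nc = config.sv_category_exposures * nc_mask
    p_nc = p_nc / p_nc.sum() if p_nc.sum() > 0 else nc_mask / nc_mask.sum()
    avail = {c: l for c, l in lengths.items() if c not in complex_set}
    for _ in range(n_bg_events):
        lab = SV32_LABELS[int(rng.choice(32, p=p_nc))]
        if lab.endswith("trans"):
            chroms = list(avail)
            i, j = rng.choice(len(chroms), size=2, replace=False)
            c1, c2 = sorted((chroms[int(i)], chroms[int(j)]))
            p1 = int(rng.integers(1, avail[c1]))
            p2 = int(rng.integers(1, avail[c2]))
            s1, s2 = rng.choice(["+", "-"], size=2)
            _add_event(c1, p1, s1, c2, p2, s2, "TRA", False)
        else:
            _, typ, bin_name = lab.split(":")
            lo, hi = _SV_BIN_RANGES[bin_name]
            hi = min(hi, 0.8 * max(avail.values()))
            if hi <= lo:
                continue
            size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            chrom = _choose_sized_chrom(rng, avail, set(), size * 1.5)
            if chrom is None:
                continue
            p1 = int(rng.integers(1, avail[chrom] - size))
            s1, s2 = rng.choice(["+", "-"], size=2)
            _add_event(chrom, p1, s1, chrom, p1 + size, s2, typ.upper(), False)

    # SNVs: kataegis clusters in TpC context, background from the mixture
    snv_rows = []
    used: set = set()
    truth_kataegis = []
    auto_avail = [c for c in AUTOSOMES if c in lengths]
    auto_w = np.array([lengths[c] for c in auto_avail], dtype=float)
    auto_w /= auto_w.sum()
    for _ in range(config.kataegis_loci):
        for _attempt in range(20):
            chrom = auto_avail[int(rng.choice(len(auto_avail), p=auto_w))]
            seq = reference[chrom]
            start = int(rng.uniform(0.05, 0.75) * lengths[chrom])
            positions = []
            p = start
            ok = True
            for _i in range(config.kataegis_cluster_size):
                gap = 1 if not positions else int(rng.exponential(config.kataegis_spacing_mean)) + 1
                i0 = seq.find(b"TC", p + gap - 1)
                if i0 < 0 or i0 + 2 > len(seq):
                    ok = False
                    break
                p = i0 + 2  # 1-based position of the C
                positions.append(p)
            if not ok or len(positions) < config.kataegis_cluster_size:
                continue
            imd = np.diff(positions)
            if imd.mean() > 900:
                continue
            if any(pos in used for pos in positions):
                continue
            for pos in positions:
                used.add(pos)
                alt = "T" if rng.random() < 0.7 else "G"
                snv_rows.append((chrom, pos, "C", alt))
            truth_kataegis.append(
                (chrom, positions[0], positions[-1], len(positions), float(imd.mean()))
            )
            break

    S = config.sbs_signatures
    mix = S @ config.sample_exposures(sample_index)
    mix = mix / mix.sum()
    cats = rng.choice(96, size=config.snv_count, p=mix)
    all_chroms = list(lengths)
    all_w = np.array([lengths[c] for c in all_chroms], dtype=float)
    all_w /= all_w.sum()
    for c in cats:
        sub = _SUBS[c // 16]
        ref, alt = sub.split(">")
        tri = (_BASES[(c % 16) // 4] + ref + _BASES[c % 4]).encode()
        rc = tri.decode().translate(str.maketrans("ACGT", "TGCA"))[::-1].encode()
        placed = False
        for _try in range(40):
            chrom = all_chroms[int(rng.choice(len(all_chroms), p=all_w))]
            seq = reference[chrom]
            p = int(rng.integers(2, lengths[chrom] - 1))
            ctx = seq[p - 2 : p + 1]
            if ctx == tri and (chrom, p) not in used:
                snv_rows.append((chrom, p, ref, alt))
            elif ctx == rc and (chrom, p) not in used:
                snv_rows.append((chrom, p, _COMP[ref], _COMP[alt]))
            else:
                continue
            used.add((chrom, p))
            placed = True
            break
        if not placed:  # fall back to a directed search
            chrom = all_chroms[int(rng.choice(len(all_chroms), p=all_w))]
            seq = reference[chrom]
            off = int(rng.integers(0, lengths[chrom]))
            i0 = seq.find(tri, off)
            if i0 < 0:
                i0 = seq.find(tri)
            if i0 >= 0 and (chrom, i0 + 2) not in used:
                snv_rows.append((chrom, i0 + 2, ref, alt))
                used.add((chrom, i0 + 2))

    # assemble outputs
    seg_rows = []
    for chrom in build.chrom_names:
        for s, e, t, m in chrom_segs[chrom].segs:
            seg_rows.append((chrom, s, e, t, m))
    profile = SegmentProfile(
        sid,
        pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "total_cn", "minor_cn"]),
        ploidy,
        purity,
    )
    rearr = RearrangementSet(
        sid,
        pd.DataFrame(
            events,
            columns=["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2", "sv_type"],
        ),
    )
    snvs = SnvSet(sid, pd.DataFrame(snv_rows, columns=["chrom", "pos", "ref", "alt"]))

    auto = profile.autosomal()
    seg_len = (auto["end"] - auto["start"] + 1).to_numpy(dtype=float)
    major = (auto["total_cn"] - auto["minor_cn"]).to_numpy()
    wgd_fraction = float(seg_len[major >= 2].sum() / seg_len.sum())

    cat_index = {lab: i for i, lab in enumerate(SV32_LABELS)}
    sv32_counts = np.zeros(32, dtype=np.int64)
    for lab in truth_cats:
        sv32_counts[cat_index[lab]] += 1

    truth = TruthLabels(
        sample_id=sid,
        wgd=wgd,
        wgd_fraction=wgd_fraction,
        ploidy=ploidy,
        arm_calls=truth_arms,
        complex_chroms=truth_complex,
        kataegis_loci=truth_kataegis,
        exposures=config.sample_exposures(sample_index).copy(),
        sv32_counts=sv32_counts,
    )
    return profile, rearr, snvs, reference, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig, outdir) -> pd.DataFrame:
    """Simulate a cohort to disk; returns the manifest table.

    Writes per sample ``<sid>.segments.tsv``, ``<sid>.bedpe``,
    ``<sid>.vcf``, a shared ``reference.fa``, a ``manifest.tsv``, flat
    truth tables and the cohort-level expected SV32 / SBS96 feature
    matrices.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = simulate_reference(config)
    write_fasta({c: s.decode() for c, s in reference.items()}, outdir / "reference.fa")

    manifest_rows = []
    truth_rows = []
    arm_rows = []
    kat_rows = []
    exp_rows = []
    sv_truth = {}
    for i in range(config.n_samples):
        profile, rearr, snvs, _, truth = simulate_sample(config, i, reference=reference)
        sid = truth.sample_id
        seg_path = outdir / f"{sid}.segments.tsv"
        sv_path = outdir / f"{sid}.bedpe"
        vcf_path = outdir / f"{sid}.vcf"
        write_segments(profile, seg_path)
        write_bedpe(rearr, sv_path)
        write_vcf(snvs, vcf_path, build=config.genome)
        manifest_rows.append((sid, seg_path.name, sv_path.name, vcf_path.name))
        truth_rows.append(
            (
                sid, truth.wgd, truth.wgd_fraction, truth.ploidy,
                sum(1 for v in truth.arm_calls.values() if v != "neutral"),
                ";".join(f"{c}={v}" for c, v in sorted(truth.complex_chroms.items())),
                len(truth.kataegis_loci),
            )
        )
        for arm, call in sorted(truth.arm_calls.items()):
            arm_rows.append((sid, arm, call))
        for chrom, start, end, n, mean_imd in truth.kataegis_loci:
            kat_rows.append((sid, chrom, start, end, n, mean_imd))
        exp_rows.append((sid, *truth.exposures))
        sv_truth[sid] = truth.sv32_counts

    manifest = pd.DataFrame(
        manifest_rows, columns=["sample", "segments", "bedpe", "vcf"]
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    pd.DataFrame(
        truth_rows,
        columns=[
            "sample", "wgd", "wgd_fraction", "ploidy",
            "n_altered_arms", "complex_chroms", "n_kataegis_loci",
        ],
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    pd.DataFrame(arm_rows, columns=["sample", "arm", "call"]).to_csv(
        outdir / "truth_arm_calls.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        kat_rows, columns=["sample", "chrom", "start", "end", "n_mutations", "mean_imd"]
    ).to_csv(outdir / "truth_kataegis.tsv", sep="\t", index=False)
    k = np.atleast_2d(config.exposures).shape[1]
    pd.DataFrame(
        exp_rows, columns=["sample"] + [f"sig{j + 1}" for j in range(k)]
    ).to_csv(outdir / "truth_exposures.tsv", sep="\t", index=False)

    if sv_truth:
        from .genome_io import write_feature_matrix

        fm = FeatureMatrix.from_columns("SV32", sv_truth)
        write_feature_matrix(fm, outdir / "truth_sv32.tsv")
        mix = config.sbs_signatures @ np.atleast_2d(config.exposures).T  # 96 x n
        expected = {
            sid: config.snv_count * (mix[:, 0] if mix.shape[1] == 1 else mix[:, j])
            for j, sid in enumerate(s for s, *_ in manifest_rows)
        }
        exp_df = pd.DataFrame(expected, index=list(SBS96_LABELS))
        exp_df.to_csv(outdir / "truth_sbs96_expected.tsv", sep="\t", index_label="category")
    return manifest


# ---------------------------------------------------------------------------
# Catalog-level simulation (for signature-inference studies)
# ---------------------------------------------------------------------------


def simulate_catalog(
    scheme: str,
    signatures: np.ndarray,
    exposures: np.ndarray,
    total_counts,
    seed: int = 0,
    noise: str = "poisson",
) -> FeatureMatrix:
    """Draw a categories x samples count matrix from planted signatures.

    ``signatures`` is categories x K with columns summing to 1;
    ``exposures`` is samples x K (rows summing to 1); ``total_counts`` is
    the expected number of events per sample (scalar or per-sample).  With
    ``noise='poisson'`` counts are Poisson around the expected mixture;
    with ``noise='multinomial'`` each sample draws exactly its total.
    """
    rng = np.random.default_rng(seed)
    W = np.asarray(signatures, dtype=float)
    E = np.atleast_2d(np.asarray(exposures, dtype=float))
    if (E < 0).any() or not np.allclose(E.sum(axis=1), 1.0, atol=1e-8):
        raise ConfigError("exposure rows must be nonnegative and sum to 1")
    n = E.shape[0]
    totals = np.broadcast_to(np.asarray(total_counts, dtype=float), (n,))
    cols = {}
    for j in range(n):
        mean = W @ E[j]
        mean = mean / mean.sum()
        if noise == "poisson":
            cols[f"S{j:03d}"] = rng.poisson(totals[j] * mean)
        elif noise == "multinomial":
            cols[f"S{j:03d}"] = rng.multinomial(int(totals[j]), mean)
        else:
            raise ConfigError(f"unknown noise model {noise!r}")
    return FeatureMatrix.from_columns(scheme, cols)
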