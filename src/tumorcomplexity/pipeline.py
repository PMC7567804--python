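"""Cohort-level orchestration: simulate -> features -> signatures -> ploidy
-> complexity -> annotate, with config echo and per-stage status.

Every stage is an ordinary function over the library types; :func:`run_cohort`
chains them over a cohort directory produced by the simulator (or any
directory with a compatible manifest) and writes one output file per stage
plus a provenance record.  A failing stage is recorded in ``stages.tsv``
and aborts the run with partial outputs retained.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genome_io import (
    GenomeBuild,
    grch37_build,
    load_genome_build,
    mini_build,
    read_sample,
    write_feature_matrix,
)
from .feature_catalogs import FeatureMatrix, build_sbs96, classify_cn40, classify_sv32, cluster_breakpoints
from .ploidy_aneuploidy import call_arm_events, ploidy_report
from .complexity import classify_sample_complexity, detect_kataegis
from .locus_annotation import bin_breakpoints_1mb, compute_tmb
from .signature_inference import extract_signatures, refit_exposures
from .synthetic_cohort import SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "run_cohort", "resolve_build"]


@dataclass
class RunConfig:
    """Everything one cohort run needs; defaults are materialized into
    the provenance record so reruns are self-describing."""

    outdir: str = "cohort_out"
    seed: int = 0
    genome: str = "mini"  # mini | grch37 | path to an arm table
    manifest: str | None = None  # existing cohort; None -> simulate
    n_samples: int = 10
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    cluster_distance: float = 1e6
    min_cluster_size: int = 10
    pcf_gamma: float = 25.0
    nmf_ranks: list = field(default_factory=lambda: [2, 3, 4, 5, 6])
    nmf_runs: int = 30
    nmf_randomized_runs: int = 30
    exposure_threshold: float = 0.15
    min_mutations: int = 50

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def resolve_build(name: str) -> GenomeBuild:
    if name == "mini":
        return mini_build()
    if name == "grch37":
        return grch37_build()
    return load_genome_build(name)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_cohort(config: RunConfig) -> Path:
    """Run the full per-cohort analysis; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    build = resolve_build(config.genome)
    status = []

    def _record(stage, state, detail=""):
        status.append((stage, state, detail))
        pd.DataFrame(status, columns=["stage", "status", "detail"]).to_csv(
            outdir / "stages.tsv", sep="\t", index=False
        )

    provenance = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
    }
    (outdir / "provenance.yaml").write_text(yaml.safe_dump(provenance, sort_keys=True))

    try:
        if config.manifest is None:
            sim = SimulationConfig(
                seed=config.seed,
                n_samples=config.n_samples,
                genome=build,
                **config.simulation,
            )
            cohort_dir = outdir / "cohort"
            manifest = simulate_cohort(sim, cohort_dir)
            _record("simulate", "ok", f"{len(manifest)} samples")
        else:
            cohort_dir = Path(config.manifest).parent
            manifest = pd.read_csv(config.manifest, sep="\t")
            _record("simulate", "skipped", "using existing manifest")
    except Exception as e:  # noqa: BLE001
        _record("simulate", "failed", str(e))
        raise

    samples = {}
    try:
        for r in manifest.itertuples():
            samples[r.sample] = read_sample(
                cohort_dir / r.segments,
                cohort_dir / r.bedpe,
                cohort_dir / r.vcf,
                build=build,
                sample_id=r.sample,
            )
        _record("genome_io", "ok", f"{len(samples)} samples read")
    except Exception as e:  # noqa: BLE001
        _record("genome_io", "failed", str(e))
        raise

    try:
        reference = cohort_dir / "reference.fa"
        sv_cols, cn_cols, sbs_cols = {}, {}, {}
        for sid, (profile, rearr, snvs) in samples.items():
            flags = cluster_breakpoints(
                rearr, config.cluster_distance, config.min_cluster_size
            )
            sv_cols[sid] = classify_sv32(rearr, flags)
            cn_cols[sid] = classify_cn40(profile)
            if reference.exists():
                sbs_cols[sid], _ = build_sbs96(snvs, reference)
        matrices = {"SV32": FeatureMatrix.from_columns("SV32", sv_cols),
                    "CN40": FeatureMatrix.from_columns("CN40", cn_cols)}
        if sbs_cols:
            matrices["SBS96"] = FeatureMatrix.from_columns("SBS96", sbs_cols)
        for scheme, fm in matrices.items():
            write_feature_matrix(fm, outdir / f"features_{scheme.lower()}.tsv")
        _record("features", "ok", ",".join(matrices))
    except Exception as e:  # noqa: BLE001
        _record("features", "failed", str(e))
        raise

    try:
        for scheme, fm in matrices.items():
            if len(fm.samples) < 3:
                continue
            model = extract_signatures(
                fm,
                ranks=config.nmf_ranks,
                n_runs=config.nmf_runs,
                n_randomized_runs=config.nmf_randomized_runs,
                seed=config.seed,
            )
            model.W.to_csv(outdir / f"signatures_{scheme.lower()}_W.tsv", sep="\t")
            model.rank_diagnostics.to_csv(
                outdir / f"signatures_{scheme.lower()}_ranks.tsv", sep="\t"
            )
            rows = []
            for sid in fm.samples:
                ev = refit_exposures(
                    fm.counts[sid].to_numpy(), model.W,
                    threshold=config.exposure_threshold,
                    min_mutations=config.min_mutations,
                    sample_id=sid,
                )
                row = {"sample": sid, "unassigned": ev.unassigned}
                row.update(ev.exposures)
                rows.append(row)
            pd.DataFrame(rows).fillna(0.0).to_csv(
                outdir / f"exposures_{scheme.lower()}.tsv", sep="\t", index=False
            )
        _record("signatures", "ok")
    except Exception as e:  # noqa: BLE001
        _record("signatures", "failed", str(e))
        raise

    try:
        rows, arm_rows = [], []
        for sid, (profile, rearr, snvs) in samples.items():
            rep = ploidy_report(profile, build)
            rows.append(
                (sid, rep.wgd, rep.wgd_fraction, rep.aneuploidy_score,
                 rep.altered_genome_fraction)
            )
            arms = call_arm_events(profile, build, presplit=True)
            for arm, r in arms.calls.iterrows():
                arm_rows.append((sid, arm, r["call"], r["altered_fraction_gain"],
                                 r["altered_fraction_loss"]))
        pd.DataFrame(
            rows,
            columns=["sample", "wgd", "wgd_fraction", "aneuploidy_score",
                     "altered_genome_fraction"],
        ).to_csv(outdir / "ploidy.tsv", sep="\t", index=False)
        pd.DataFrame(
            arm_rows,
            columns=["sample", "arm", "call", "fraction_gain", "fraction_loss"],
        ).to_csv(outdir / "arm_calls.tsv", sep="\t", index=False)
        _record("ploidy", "ok")
    except Exception as e:  # noqa: BLE001
        _record("ploidy", "failed", str(e))
        raise

    try:
        kat_rows, cx_rows = [], []
        for sid, (profile, rearr, snvs) in samples.items():
            for locus in detect_kataegis(snvs, gamma=config.pcf_gamma):
                kat_rows.append((sid, locus.chrom, locus.start, locus.end,
                                 locus.n_mutations, locus.mean_imd))
            for call in classify_sample_complexity(profile, rearr, build):
                cx_rows.append(
                    (sid, call.chrom, call.candidate, call.call, call.clustered_p,
                     call.breakpoint_count, call.translocation_count,
                     call.telomeric_loss, call.foldback_count, call.cn_switches,
                     call.cn_states, call.het_retention_fraction)
                )
        pd.DataFrame(
            kat_rows,
            columns=["sample", "chrom", "start", "end", "n_mutations", "mean_imd"],
        ).to_csv(outdir / "kataegis.tsv", sep="\t", index=False)
        pd.DataFrame(
            cx_rows,
            columns=["sample", "chrom", "candidate", "call", "clustered_p",
                     "breakpoint_count", "translocation_count", "telomeric_loss",
                     "foldback_count", "cn_switches", "cn_states",
                     "het_retention_fraction"],
        ).to_csv(outdir / "complex_chromosomes.tsv", sep="\t", index=False)
        _record("complexity", "ok")
    except Exception as e:  # noqa: BLE001
        _record("complexity", "failed", str(e))
        raise

    try:
        genome_mb = sum(build.chrom_lengths.values()) / 1e6
        rows = []
        for sid, (profile, rearr, snvs) in samples.items():
            rows.append(
                (sid, compute_tmb(len(snvs.variants), genome_mb), len(rearr.events))
            )
        pd.DataFrame(
            rows, columns=["sample", "tmb", "rearrangement_count"]
        ).to_csv(outdir / "sample_summary.tsv", sep="\t", index=False)
        bins = bin_breakpoints_1mb([s[1] for s in samples.values()], build)
        bins.to_csv(outdir / "breakpoint_bins_1mb.tsv", sep="\t", index=False)
        _record("annotate", "ok")
    except Exception as e:  # noqa: BLE001
        _record("annotate", "failed", str(e))
        raise

    return outdir
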