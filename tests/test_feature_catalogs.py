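"""SBS96 / SV32 / CN40 category schemes and counting conservation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tumorcomplexity.genome_io import ConfigError, RearrangementSet, SnvSet, write_fasta
from tumorcomplexity.feature_catalogs import (
    CN40_LABELS,
    SBS96_LABELS,
    SV32_LABELS,
    build_sbs96,
    classify_cn40,
    classify_sv32,
    cluster_breakpoints,
    cn40_category,
    sbs96_label,
    sv32_category,
)
from tumorcomplexity.synthetic_cohort import SimulationConfig, simulate_sample

from conftest import random_profile


def _rearr(rows):
    return RearrangementSet(
        "s",
        pd.DataFrame(rows, columns=["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2", "sv_type"]),
    )


class TestSchemes:
    def test_category_vocabulary_sizes(self):
        assert len(SBS96_LABELS) == 96
        assert len(SV32_LABELS) == 32
        assert len(CN40_LABELS) == 40

    def test_cn40_excludes_impossible_combinations(self):
        # het needs total >= 2; homdel is total 0 only
        assert not any(lab.startswith("het:deleted") for lab in CN40_LABELS)
        assert sum(lab.startswith("homdel") for lab in CN40_LABELS) == 5
        assert sum(lab.startswith("LOH") for lab in CN40_LABELS) == 20
        assert sum(lab.startswith("het") for lab in CN40_LABELS) == 15


class TestSbs96:
    def test_single_mutation_in_known_context(self, tmp_path):
        write_fasta({"1": "AACGT"}, tmp_path / "r.fa")
        snvs = SnvSet("s", pd.DataFrame([("1", 3, "C", "T")], columns=["chrom", "pos", "ref", "alt"]))
        counts, excluded = build_sbs96(snvs, tmp_path / "r.fa")
        assert excluded == 0 and counts.sum() == 1
        assert counts[SBS96_LABELS.index("A[C>T]G")] == 1

    def test_purine_reference_reverse_complemented(self, tmp_path):
        # reference strand context C G T around a G>A; pyrimidine class A[C>T]G
        write_fasta({"1": "ACGTA"}, tmp_path / "r.fa")
        snvs = SnvSet("s", pd.DataFrame([("1", 3, "G", "A")], columns=["chrom", "pos", "ref", "alt"]))
        counts, _ = build_sbs96(snvs, tmp_path / "r.fa")
        assert counts[SBS96_LABELS.index("A[C>T]G")] == 1
        assert sbs96_label("CGT", "G", "A") == "A[C>T]G"

    def test_context_with_n_excluded(self, tmp_path):
        write_fasta({"1": "ANCGT"}, tmp_path / "r.fa")
        snvs = SnvSet("s", pd.DataFrame([("1", 3, "C", "T")], columns=["chrom", "pos", "ref", "alt"]))
        counts, excluded = build_sbs96(snvs, tmp_path / "r.fa")
        assert counts.sum() == 0 and excluded == 1

    def test_simulated_catalog_matches_planted_mixture(self, micro, tmp_path):
        """Empirical SBS96 frequencies stay inside the 99% multinomial
        envelope of the generating signature mixture."""
        from tumorcomplexity.synthetic_cohort import synthetic_sbs_signatures

        W = synthetic_sbs_signatures(2)
        cfg = SimulationConfig(
            seed=21, n_samples=1, genome=micro, snv_count=5000,
            kataegis_loci=0, sbs_signatures=W, exposures=np.array([0.7, 0.3]),
        )
        profile, rearr, snvs, reference, truth = simulate_sample(cfg, 0)
        fa = tmp_path / "ref.fa"
        write_fasta({c: s.decode() for c, s in reference.items()}, fa)
        counts, excluded = build_sbs96(snvs, fa)
        assert excluded == 0
        n = counts.sum()
        assert n == len(snvs.variants)
        p = W @ np.array([0.7, 0.3])
        lo = stats.binom.ppf(0.005, n, p)
        hi = stats.binom.ppf(0.995, n, p)
        outside = int(((counts < lo) | (counts > hi)).sum())
        # 96 marginal checks at 1% two-sided: a few excursions expected
        assert outside <= 4


class TestClustering:
    def test_dense_window_flagged_clustered(self):
        rows = [("1", 10_000 + 40_000 * i, "+", "1", 20_000 + 40_000 * i, "-", "DEL") for i in range(10)]
        rs = _rearr(rows)  # 20 ends within 400 kb
        flags = cluster_breakpoints(rs, distance_d=1e6, min_cluster_size=10)
        assert flags.all()

    def test_isolated_breakpoints_not_clustered(self):
        rs = _rearr([("1", 1_000_000, "+", "1", 51_000_000, "-", "DEL")])
        assert not cluster_breakpoints(rs, 1e6, 10).any()

    def test_zero_distance_degenerates_to_singletons(self):
        rows = [("1", 1000 + i, "+", "1", 5_000_000 + i, "-", "DEL") for i in range(20)]
        assert not cluster_breakpoints(_rearr(rows), distance_d=0, min_cluster_size=2).any()

    def test_negative_distance_rejected(self):
        with pytest.raises(ConfigError):
            cluster_breakpoints(_rearr([]), distance_d=-1)


class TestSv32:
    @pytest.mark.parametrize(
        "typ,size,clustered,expected",
        [
            ("DEL", 5_000, False, "non-clustered:del:1-10kb"),
            ("DEL", 500, False, "non-clustered:del:1-10kb"),  # sub-kb shares smallest bin
            ("DUP", 10_000, False, "non-clustered:dup:10-100kb"),  # half-open boundary
            ("INV", 10_000_000, True, "clustered:inv:>10Mb"),
            ("TRA", None, True, "clustered:trans"),
            ("TRA", None, False, "non-clustered:trans"),
        ],
    )
    def test_category_assignment(self, typ, size, clustered, expected):
        assert sv32_category(typ, size, clustered) == expected

    def test_column_sums_to_event_count(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(60):
            if rng.random() < 0.3:
                rows.append(("1", int(rng.integers(1, 9e6)), "+", "2", int(rng.integers(1, 5e6)), "-", "TRA"))
            else:
                p = int(rng.integers(1, 8e6))
                typ = ["DEL", "DUP", "INV"][int(rng.integers(3))]
                rows.append(("1", p, "+", "1", p + int(rng.integers(1, 1e6)), "-", typ))
        rs = _rearr(rows)
        counts = classify_sv32(rs)
        assert counts.sum() == 60 and (counts >= 0).all()


class TestCn40:
    @pytest.mark.parametrize(
        "total,minor,length,expected",
        [
            (0, 0, 500_000, "homdel:deleted:0.1-1Mb"),
            (3, 1, 15_000_000, "het:duplicated:>10Mb"),
            (1, 0, 5_000, "LOH:deleted:0-0.01Mb"),
            (2, 0, 10_000, "LOH:neutral:0.01-0.1Mb"),  # exactly 0.01 Mb, half-open
            (8, 0, 2_000_000, "LOH:amplified:1-10Mb"),
            (2, 1, 100, "het:neutral:0-0.01Mb"),
        ],
    )
    def test_category_assignment(self, total, minor, length, expected):
        assert cn40_category(total, minor, length) == expected

    def test_conservation_on_random_profiles(self, toy_build):
        """Every segment lands in exactly one in-vocabulary category."""
        for seed in range(100):
            prof = random_profile(toy_build, np.random.default_rng(seed))
            counts = classify_cn40(prof)
            assert counts.sum() == len(prof.segments)


class TestClassificationTotality:
    """Any syntactically valid input maps into the vocabulary (property)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        total=st.integers(0, 30),
        frac=st.floats(0, 1),
        length=st.integers(1, 2_000_000_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_cn40_classification_is_total(self, total, frac, length):
        minor = int(frac * (total // 2))
        assert cn40_category(total, minor, length) in CN40_LABELS

    @given(
        typ=st.sampled_from(["DEL", "DUP", "INV"]),
        size=st.integers(1, 500_000_000),
        clustered=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_sv32_classification_is_total(self, typ, size, clustered):
        assert sv32_category(typ, size, clustered) in SV32_LABELS

    @given(
        five=st.sampled_from("ACGT"),
        ref=st.sampled_from("ACGT"),
        three=st.sampled_from("ACGT"),
        alt=st.sampled_from("ACGT"),
    )
    @settings(max_examples=200, deadline=None)
    def test_sbs96_label_is_total_over_contexts(self, five, ref, three, alt):
        if alt == ref:
            return
        assert sbs96_label(five + ref + three, ref, alt) in SBS96_LABELS
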