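"""Kataegis segmentation, candidate flags and BFB/chromothripsis calls."""

from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tumorcomplexity.genome_io import ConfigError, RearrangementSet, SnvSet
from tumorcomplexity.complexity import (
    classify_complex_chromosome,
    classify_sample_complexity,
    detect_candidate_chromosomes,
    detect_kataegis,
    fit_pcf,
)
from tumorcomplexity.synthetic_cohort import SimulationConfig, simulate_reference, simulate_sample

from conftest import make_profile


def _snvs(positions, chrom="1"):
    return SnvSet(
        "s",
        pd.DataFrame(
            [(chrom, int(p), "C", "T") for p in positions],
            columns=["chrom", "pos", "ref", "alt"],
        ),
    )


def _rearr(rows):
    return RearrangementSet(
        "s",
        pd.DataFrame(rows, columns=["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2", "sv_type"]),
    )


def _pcf_cost_oracle(x, gamma):
    """Minimum segmentation cost by exhaustive enumeration of boundary sets."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    best = np.inf
    for k in range(n):
        for cuts in combinations(range(1, n), k):
            bounds = [0, *cuts, n]
            cost = 0.0
            for a, b in zip(bounds[:-1], bounds[1:]):
                seg = x[a:b]
                cost += ((seg - seg.mean()) ** 2).sum() + gamma
            best = min(best, cost)
    return best


def _segment_cost(segments, x, gamma):
    return sum(
        ((x[a : b + 1] - x[a : b + 1].mean()) ** 2).sum() + gamma for a, b in segments
    )


class TestPcf:
    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        x = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(4, 1, n - n // 2)])
        gamma = float(rng.uniform(0.5, 10))
        segs = fit_pcf(x, gamma)
        assert segs[0][0] == 0 and segs[-1][1] == n - 1
        assert _segment_cost(segs, x, gamma) == pytest.approx(
            _pcf_cost_oracle(x, gamma), rel=1e-10
        )

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_memoized_recursion_on_longer_series(self, seed):
        """Independent recursive oracle over all segmentations, n <= 30."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(10, 31))
        x = rng.normal(0, 2, n)
        gamma = float(rng.uniform(1, 30))

        @lru_cache(maxsize=None)
        def best(j):  # minimal cost of segmenting x[0:j]
            if j == 0:
                return 0.0
            out = np.inf
            for i in range(j):
                seg = x[i:j]
                out = min(out, best(i) + ((seg - seg.mean()) ** 2).sum() + gamma)
            return out

        assert _segment_cost(fit_pcf(x, gamma), x, gamma) == pytest.approx(
            best(n), rel=1e-10
        )

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ConfigError):
            fit_pcf(np.ones(5), 0.0)
        with pytest.raises(ConfigError):
            detect_kataegis(_snvs([1, 2]), gamma=-1)


class TestKataegis:
    def test_tight_cluster_in_sparse_background(self):
        bg = list(range(1_000_000, 30_000_001, 1_000_000))
        cluster = [40_000_000 + 500 * i for i in range(10)]
        loci = detect_kataegis(_snvs(sorted(bg + cluster)))
        assert len(loci) == 1
        l = loci[0]
        assert (l.start, l.end, l.n_mutations) == (40_000_000, 40_004_500, 10)
        assert l.mean_imd == pytest.approx(500.0)

    def test_five_mutations_insufficient(self):
        loci = detect_kataegis(_snvs([100, 200, 300, 400, 500]))
        assert loci == []

    def test_uniform_wide_spacing_yields_no_locus(self):
        loci = detect_kataegis(_snvs(range(10_000, 500_001, 10_000)))
        assert loci == []

    def test_imd_not_computed_across_chromosomes(self):
        # 3 close mutations on each of two chromosomes: no 6-run anywhere
        v = pd.concat([_snvs([100, 200, 300], "1").variants,
                       _snvs([100, 200, 300], "2").variants])
        assert detect_kataegis(SnvSet("s", v)) == []

    def test_planted_loci_recovered_without_false_calls(self, mini):
        cfg = SimulationConfig(seed=31, genome=mini, snv_count=310,
                               kataegis_loci=2, kataegis_cluster_size=8)
        ref = simulate_reference(cfg)
        found = planted = extra = 0
        for i in range(10):
            _, _, snvs, _, truth = simulate_sample(cfg, i, reference=ref)
            loci = detect_kataegis(snvs)
            hits = 0
            for (c, s, e, n, m) in truth.kataegis_loci:
                planted += 1
                hit = any(l.chrom == c and l.start <= e and l.end >= s for l in loci)
                found += hit
                hits += hit
            extra += len(loci) - hits
        assert planted == 20 and found >= 19
        assert extra == 0


class TestCandidateFlags:
    def test_uniform_breakpoints_not_flagged(self, mini):
        rng = np.random.default_rng(0)
        L = mini.chrom_lengths["1"]
        rows = []
        pos = np.sort(rng.integers(1, L, size=100))
        for i in range(0, 100, 2):
            rows.append(("1", int(pos[i]), "+", "1", int(pos[i + 1]), "-", "DUP"))
        flags = detect_candidate_chromosomes(_rearr(rows), mini)
        assert not flags.loc["1", "flag_clustered"]

    def test_confined_breakpoints_flagged(self, mini):
        # 50 ends inside a 5% window of the chromosome: KS distance ~ 0.9
        L = mini.chrom_lengths["1"]
        rng = np.random.default_rng(1)
        rows = []
        pos = np.sort(rng.integers(L // 2, L // 2 + L // 20, size=50))
        for i in range(0, 50, 2):
            rows.append(("1", int(pos[i]), "+", "1", int(pos[i + 1]), "-", "INV"))
        flags = detect_candidate_chromosomes(_rearr(rows), mini)
        assert flags.loc["1", "flag_clustered"] and flags.loc["1", "candidate"]

    def test_translocation_threshold(self, mini):
        rows = [("5", 1_000_000 * (i + 1), "+", "8", 500_000 * (i + 1), "-", "TRA")
                for i in range(12)]
        flags = detect_candidate_chromosomes(_rearr(rows), mini)
        assert flags.loc["5", "flag_translocations"]
        assert flags.loc["8", "flag_translocations"]
        assert flags.loc["5", "candidate"]
        assert not flags.loc["1", "candidate"]

    def test_type_one_error_calibration(self, mini):
        """Uniform breakpoints are flagged at p<1e-5 in <=0.1% of simulations."""
        rng = np.random.default_rng(42)
        n, sims = 50, 2000
        L = 100_000_000
        u = rng.random((sims, n))
        d_plus = (np.arange(1, n + 1) / n - np.sort(u, axis=1)).max(axis=1)
        d_minus = (np.sort(u, axis=1) - np.arange(0, n) / n).max(axis=1)
        d = np.maximum(d_plus, d_minus)
        pvals = stats.kstwo.sf(d, n)
        assert (pvals < 1e-5).mean() <= 1e-3


class TestClassification:
    def test_translocation_only_candidate_is_localized_complex(self, mini):
        rows = [("5", 1_000_000 * (i + 1), "+", "8", 500_000 * (i + 1), "-", "TRA")
                for i in range(12)]
        rearr = _rearr(rows)
        prof = make_profile("s", [(c, 1, l, 2, 1) for c, l in mini.chrom_lengths.items()])
        flags = detect_candidate_chromosomes(rearr, mini)
        call = classify_complex_chromosome("5", prof, rearr, flags.loc["5"])
        assert call.call == "localized_complex"
        assert not call.telomeric_loss and call.cn_switches == 0

    def test_planted_complex_chromosomes_classified(self, micro):
        """Planted chromothripsis and BFB recovered on simulated samples."""
        cfg = SimulationConfig(seed=33, genome=micro, snv_count=65)
        ref = simulate_reference(cfg)
        ok = tot = 0
        for i in range(15):
            prof, rearr, _, _, truth = simulate_sample(cfg, i, reference=ref)
            calls = {c.chrom: c.call for c in classify_sample_complexity(prof, rearr, micro)}
            for chrom, cls in truth.complex_chroms.items():
                tot += 1
                ok += calls.get(chrom, "none") == cls
        assert tot == 30 and ok >= 29

    def test_no_rearrangements_yields_no_calls(self, mini):
        prof = make_profile("s", [("1", 1, 1000, 2, 1)])
        assert classify_sample_complexity(prof, _rearr([]), mini) == []
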