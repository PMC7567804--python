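import numpy as np
import pandas as pd
import pytest

from tumorcomplexity.genome_io import GenomeBuild, SegmentProfile, mini_build


@pytest.fixture(scope="session")
def mini():
    return mini_build()


@pytest.fixture(scope="session")
def micro():
    """Mini genome scaled a further 1:10 (~31 Mb) for fast simulations."""
    return mini_build().scaled(0.1, "micro")


@pytest.fixture(scope="session")
def toy_build():
    """Two small chromosomes plus an acrocentric one, for oracle tests."""
    return GenomeBuild(
        "toy",
        (
            ("1", 10_000_000, 4_000_000, 4_400_000),
            ("2", 6_000_000, 2_500_000, 2_700_000),
            ("13", 5_000_000, 1_000_000, 1_200_000),
        ),
    )


@pytest.fixture(scope="session")
def oracle_build():
    """~7 Mb three-chromosome build for per-basepair brute-force oracles."""
    return GenomeBuild(
        "oracle",
        (
            ("1", 3_300_000, 1_400_000, 1_500_000),
            ("2", 2_100_000, 900_000, 1_000_000),
            ("13", 1_600_000, 300_000, 400_000),
        ),
    )


def make_profile(sample_id, rows, ploidy=2.0, purity=0.8):
    return SegmentProfile(
        sample_id,
        pd.DataFrame(rows, columns=["chrom", "start", "end", "total_cn", "minor_cn"]),
        ploidy,
        purity,
    )


def random_profile(build, rng, max_cn=8):
    """Random valid segment profile covering every chromosome of a build."""
    rows = []
    for chrom, length in build.chrom_lengths.items():
        n_seg = int(rng.integers(1, 8))
        cuts = np.sort(rng.choice(np.arange(2, length), size=n_seg - 1, replace=False)) if n_seg > 1 else np.array([], dtype=int)
        bounds = [1] + [int(c) for c in cuts] + [length + 1]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            total = int(rng.integers(0, max_cn + 1))
            minor = int(rng.integers(0, total // 2 + 1))
            rows.append((chrom, lo, hi - 1, total, minor))
    ploidy = float(rng.choice([1.8, 2.0, 2.7, 3.5, 4.0]))
    return make_profile("R", rows, ploidy=ploidy)
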