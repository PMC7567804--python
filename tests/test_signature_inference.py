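"""NMF extraction, rank selection, reference matching and exposure refitting."""

import numpy as np
import pandas as pd
import pytest

from tumorcomplexity.genome_io import ValidationError
from tumorcomplexity.feature_catalogs import FeatureMatrix, SBS96_LABELS
from tumorcomplexity.signature_inference import (
    ExposureVector,
    _kl_divergence,
    _nmf_kl,
    cosine_similarity,
    extract_signatures,
    match_to_reference,
    refit_exposures,
)
from tumorcomplexity.synthetic_cohort import simulate_catalog, synthetic_sbs_signatures


@pytest.fixture(scope="module")
def planted():
    W = synthetic_sbs_signatures(3)
    rng = np.random.default_rng(1)
    E = rng.dirichlet([5.0, 5.0, 5.0], size=40)
    fm = simulate_catalog("SBS96", W, E, 2000, seed=2, noise="poisson")
    return W, E, fm


class TestNmfCore:
    def test_objective_decreases_and_reconstructs(self):
        rng = np.random.default_rng(0)
        V = rng.poisson(5.0, size=(30, 12)).astype(float)
        W, H, obj = _nmf_kl(V, 4, np.random.default_rng(1))
        # the monotonicity guard inside _nmf_kl would have raised otherwise
        assert obj <= _kl_divergence(V, np.outer(V.mean(1), np.ones(12)))
        assert (W >= 0).all() and (H >= 0).all()

    def test_matches_sklearn_objective_on_shared_problem(self):
        """Independent cross-check: sklearn's KL-NMF reaches a comparable
        objective on the same matrix."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(3)
        V = rng.poisson(8.0, size=(40, 15)).astype(float) + 1e-9
        _, _, ours = _nmf_kl(V, 3, np.random.default_rng(0), max_iter=2000, tol=1e-12)
        sk = NMF(3, solver="mu", beta_loss="kullback-leibler", init="random",
                 random_state=0, max_iter=2000, tol=1e-12).fit(V)
        theirs = _kl_divergence(V, sk.transform(V) @ sk.components_)
        assert ours <= theirs * 1.05 + 1.0

    def test_all_zero_matrix_rejected(self):
        fm = FeatureMatrix.from_columns("SV32", {f"s{i}": np.zeros(32) for i in range(5)})
        with pytest.raises(ValidationError):
            extract_signatures(fm, ranks=[2], n_runs=2, n_randomized_runs=2)


class TestExtraction:
    def test_planted_rank_and_signatures_recovered(self, planted):
        W, E, fm = planted
        model = extract_signatures(fm, ranks=range(2, 6), n_runs=12,
                                   n_randomized_runs=12, seed=4)
        assert model.chosen_rank == 3
        ref = pd.DataFrame(W, index=list(SBS96_LABELS), columns=["P1", "P2", "P3"])
        match = match_to_reference(model, ref)
        assert set(match["best_match"]) == {"P1", "P2", "P3"}
        assert (match["cosine"] >= 0.9).all()

    def test_same_seed_reproduces_signature_matrix(self, planted):
        _, _, fm = planted
        kw = dict(ranks=[2, 3], n_runs=5, n_randomized_runs=5, seed=9)
        m1 = extract_signatures(fm, **kw)
        m2 = extract_signatures(fm, **kw)
        assert m1.chosen_rank == m2.chosen_rank
        assert np.array_equal(m1.W.to_numpy(), m2.W.to_numpy())

    def test_iid_noise_shows_no_support_above_baseline(self):
        """Rank-selection specificity: pure noise never satisfies the
        stability rule against its randomized baseline."""
        rng = np.random.default_rng(7)
        fm = FeatureMatrix.from_columns(
            "SV32", {f"s{i}": rng.poisson(10.0, 32) for i in range(20)}
        )
        model = extract_signatures(fm, ranks=[2, 3, 4], n_runs=10,
                                   n_randomized_runs=10, seed=8)
        d = model.rank_diagnostics
        eligible = (
            (d["cophenetic"] >= 0.95) & (d["silhouette"] >= 0.8)
            & (d["cophenetic"] > d["randomized_cophenetic"])
            & (d["silhouette"] > d["randomized_silhouette"])
        )
        assert not eligible.any()

    def test_rank_above_sample_count_skipped(self, planted):
        _, _, fm = planted
        small = FeatureMatrix("SBS96", fm.counts.iloc[:, :3])
        with pytest.warns(UserWarning, match="skipped"):
            model = extract_signatures(small, ranks=[2, 5], n_runs=4,
                                       n_randomized_runs=4, seed=0)
        assert list(model.rank_diagnostics.index) == [2]


class TestMatching:
    def test_identical_and_orthogonal_vectors(self):
        a = np.zeros(96); a[0] = 1.0
        b = np.zeros(96); b[1] = 1.0
        assert cosine_similarity(a, a) == pytest.approx(1.0)
        assert cosine_similarity(a, b) == pytest.approx(0.0)

    def test_scheme_mismatch_rejected(self, planted):
        W, _, fm = planted
        model = extract_signatures(fm, ranks=[3], n_runs=5, n_randomized_runs=5, seed=1)
        bad_ref = pd.DataFrame(np.eye(40), index=range(40))
        with pytest.raises(ValidationError):
            match_to_reference(model, bad_ref)


class TestRefitting:
    @pytest.fixture(scope="class")
    def W(self):
        W = synthetic_sbs_signatures(2, seed=5)
        return pd.DataFrame(W, index=list(SBS96_LABELS), columns=["S1", "S2"])

    def test_pure_catalog_fully_assigned(self, W):
        ev = refit_exposures(1000 * W["S1"].to_numpy(), W)
        assert ev.exposures == pytest.approx({"S1": 1.0}, abs=1e-6)
        assert ev.unassigned == pytest.approx(0.0, abs=1e-6)

    def test_exact_two_component_mixture(self, W):
        v = 1000 * (0.8 * W["S1"].to_numpy() + 0.2 * W["S2"].to_numpy())
        ev = refit_exposures(v, W)
        assert ev.exposures["S1"] == pytest.approx(0.8, abs=1e-6)
        assert ev.exposures["S2"] == pytest.approx(0.2, abs=1e-6)

    def test_sub_threshold_component_goes_unassigned(self, W):
        v = 1000 * (0.9 * W["S1"].to_numpy() + 0.1 * W["S2"].to_numpy())
        ev = refit_exposures(v, W)
        assert "S2" not in ev.exposures
        assert ev.exposures["S1"] == pytest.approx(0.9, abs=1e-6)
        assert ev.unassigned == pytest.approx(0.1, abs=1e-6)

    def test_scale_invariance(self, W):
        v = 0.6 * W["S1"].to_numpy() + 0.4 * W["S2"].to_numpy()
        e1 = refit_exposures(1e2 * v, W)
        e2 = refit_exposures(1e6 * v, W)
        for k in e1.exposures:
            assert e1.exposures[k] == pytest.approx(e2.exposures[k], rel=1e-9)

    def test_low_mutation_sample_entirely_unassigned(self, W):
        ev = refit_exposures(40 * W["S1"].to_numpy(), W, min_mutations=50)
        assert ev.exposures == {} and ev.unassigned == 1.0

    def test_max_signatures_cap(self):
        W = pd.DataFrame(synthetic_sbs_signatures(4, seed=11),
                         index=list(SBS96_LABELS), columns=list("ABCD"))
        v = 1000 * (W.to_numpy() @ np.array([0.3, 0.3, 0.2, 0.2]))
        ev = refit_exposures(v, W, max_signatures=2)
        assert len(ev.exposures) == 2

    def test_exposure_vector_accounting_invariant(self):
        with pytest.raises(ValidationError):
            ExposureVector("s", {"S1": 0.5}, 0.3)

    def test_planted_exposures_recovered_within_tolerance(self):
        """>= 95% of samples recover every component >= 0.2 within +/- 0.05."""
        W = synthetic_sbs_signatures(3)
        rng = np.random.default_rng(13)
        E = rng.dirichlet([4.0, 4.0, 4.0], size=100)
        fm = simulate_catalog("SBS96", W, E, 5000, seed=14, noise="multinomial")
        Wdf = pd.DataFrame(W, index=list(SBS96_LABELS), columns=["S1", "S2", "S3"])
        ok = 0
        for j in range(100):
            ev = refit_exposures(fm.counts.iloc[:, j].to_numpy(), Wdf)
            errs = [
                abs(ev.exposures.get(f"S{k + 1}", 0.0) - E[j, k])
                for k in range(3) if E[j, k] >= 0.2
            ]
            ok += all(e <= 0.05 for e in errs)
        assert ok >= 95
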