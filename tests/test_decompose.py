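import numpy as np
import pytest

from amide1.decompose import (BACKGROUND_LABEL, INTERMOLECULAR_LABEL,
                              EvolutionSummary, NMFConfig, NMFResult,
                              component_evolution, fit_regularized_nmf,
                              l_curve_select, label_components, nmf_objective,
                              nndsvd_init, pca_variance_profile,
                              select_n_components, tsne_embed)
from amide1.errors import ParameterError
from amide1.io import canonical_grid
from amide1.preprocess import preprocess_pipeline
from amide1.synthetic import BandSpec, CohortDesign, make_band, simulate_cohort


class TestPCA:
    def test_rank_one_first_fraction_unity(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.random(20), rng.random(51))
        prof = pca_variance_profile(X)
        assert prof[0] == pytest.approx(1.0, abs=1e-9)

    def test_two_equal_power_components(self):
        # exactly orthonormal directions with equal sign-balanced power
        a, b = np.zeros(51), np.zeros(51)
        a[0], b[1] = 1.0, 1.0
        signs = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]] * 10)
        X = signs @ np.vstack([a, b])
        prof = pca_variance_profile(X)
        assert prof[0] == pytest.approx(0.5, abs=1e-9)
        assert prof[1] == pytest.approx(1.0, abs=1e-9)

    def test_low_noise_cohort_five_components(self):
        design = CohortDesign(n_cells=25, noise_sd=0.001, seed=2)
        ds, _ = simulate_cohort(design)
        prof = pca_variance_profile(preprocess_pipeline(ds).matrix())
        assert prof[4] >= 0.999
        assert select_n_components(prof, 0.999) <= 5

    def test_select_smallest_k(self):
        assert select_n_components([0.8, 0.9999, 1.0], 0.9997) == 2
        assert select_n_components([1.0], 0.5) == 1

    def test_select_threshold_above_one_rejected(self):
        with pytest.raises(ParameterError):
            select_n_components([0.5, 1.0], 1.1)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ParameterError):
            pca_variance_profile(np.ones((5, 10)))  # rank 0 after centering


class TestNNDSVD:
    def test_rank_one_nonnegative_matrix_reconstructed(self):
        rng = np.random.default_rng(1)
        w, h = rng.random(15) + 0.1, rng.random(51) + 0.1
        X = np.outer(w, h)
        W0, H0 = nndsvd_init(X, 1)
        rel = np.linalg.norm(X - W0 @ H0) / np.linalg.norm(X)
        assert rel < 1e-8

    def test_negative_entry_rejected(self):
        X = np.ones((4, 5))
        X[0, 0] = -1e-9
        with pytest.raises(ParameterError):
            nndsvd_init(X, 2)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.random((20, 30))
        a = nndsvd_init(X, 4)
        b = nndsvd_init(X, 4)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_factors_nonnegative(self):
        X = np.random.default_rng(3).random((12, 17))
        W0, H0 = nndsvd_init(X, 5)
        assert W0.min() >= 0 and H0.min() >= 0

    def test_k_too_large_rejected(self):
        with pytest.raises(ParameterError):
            nndsvd_init(np.ones((3, 4)), 5)


class TestObjective:
    def test_exact_factorization_unregularized_is_zero(self):
        rng = np.random.default_rng(4)
        W, H = rng.random((6, 2)), rng.random((2, 9))
        assert nmf_objective(W @ H, W, H, 0.0, 0.0) == pytest.approx(0.0,
                                                                     abs=1e-12)

    def test_identity_worked_example(self):
        """I = I @ I with alpha=1e-2, rho=1e-3: value is exactly
        4*alpha*rho + 2*alpha*(1-rho) = 0.02002."""
        I2 = np.eye(2)
        val = nmf_objective(I2, I2, I2, 1e-2, 1e-3)
        assert val == pytest.approx(0.02002, abs=1e-12)

    def test_all_zero_is_zero(self):
        Z = np.zeros((3, 4))
        assert nmf_objective(Z, np.zeros((3, 2)), np.zeros((2, 4)),
                             1e-2, 1e-3) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            nmf_objective(np.ones((3, 4)), np.ones((3, 2)), np.ones((3, 4)),
                          0.0, 0.0)


class TestFit:
    def test_trace_matches_oracle_and_monotone_on_random_instances(self):
        """Solver-internal objective trace equals the independent objective
        evaluation (to 1e-9 relative) and never increases."""
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(5, 31))
            m = int(rng.integers(5, 31))
            k = int(rng.integers(1, 6))
            X = rng.random((n, m))
            cfg = NMFConfig(k=min(k, min(n, m)), alpha=1e-2, rho=1e-3,
                            tol=1e-6, max_iter=60)
            res = fit_regularized_nmf(X, cfg)
            final = nmf_objective(X, res.W, res.H, cfg.alpha, cfg.rho)
            assert abs(res.objective_trace[-1] - final) <= 1e-9 * final
            assert np.all(np.diff(res.objective_trace) <= 1e-12)

    def test_planted_two_component_recovery(self):
        rng = np.random.default_rng(5)
        Wt = rng.random((40, 2))
        Ht = np.vstack([make_band(BandSpec(1630.0, 20.0, 1.0),
                                  canonical_grid()).intensity,
                        make_band(BandSpec(1665.0, 20.0, 1.0),
                                  canonical_grid()).intensity])
        X = Wt @ Ht
        res = fit_regularized_nmf(X, NMFConfig(k=2, alpha=0.0, tol=1e-10,
                                               max_iter=500))
        rel = np.linalg.norm(X - res.W @ res.H) / np.linalg.norm(X)
        assert rel < 1e-3

    def test_rank_one_converges_fast(self):
        rng = np.random.default_rng(6)
        X = np.outer(rng.random(30) + 0.1, rng.random(51) + 0.1)
        res = fit_regularized_nmf(X, NMFConfig(k=1, alpha=0.0, tol=1e-10,
                                               max_iter=200))
        assert res.n_iter <= 50
        rel = np.linalg.norm(X - res.W @ res.H) / np.linalg.norm(X)
        assert rel < 1e-6

    def test_nonconvergence_flagged(self):
        X = np.random.default_rng(7).random((20, 20))
        res = fit_regularized_nmf(X, NMFConfig(k=3, tol=1e-16, max_iter=5))
        assert res.converged is False and res.n_iter == 5

    def test_normalized_preserves_product(self):
        X = np.random.default_rng(8).random((15, 20))
        res = fit_regularized_nmf(X, NMFConfig(k=3, max_iter=50))
        norm = res.normalized()
        np.testing.assert_allclose(norm.W @ norm.H, res.W @ res.H,
                                   atol=1e-10)
        assert np.all(norm.H.max(axis=1) <= 1.0 + 1e-12)

    def test_negative_matrix_rejected(self):
        with pytest.raises(ParameterError):
            fit_regularized_nmf(-np.ones((4, 4)), NMFConfig(k=1))


class TestLCurve:
    def test_single_point_grid_returned(self):
        X = np.random.default_rng(9).random((10, 12))
        assert l_curve_select(X, 2, [1e-2], [1e-3]) == (1e-2, 1e-3)

    def test_degenerate_alpha_grid_rejected(self):
        X = np.random.default_rng(9).random((10, 12))
        with pytest.raises(ParameterError):
            l_curve_select(X, 2, [1e-3, 1e-2], [1e-3])

    def test_low_rank_with_noise_prefers_moderate_alpha(self):
        """On clean low-rank data the corner stays off the high end of a
        wide alpha sweep."""
        rng = np.random.default_rng(10)
        X = np.outer(rng.random(30), rng.random(40))
        X = X + 0.01 * rng.random(X.shape)
        alphas = list(np.logspace(-4, 1, 6))
        alpha, rho = l_curve_select(X, 2, alphas, [1e-3],
                                    tol=1e-5, max_iter=300)
        assert alpha < alphas[-1]


class TestLabels:
    def test_beta_doublet_labeled_intermolecular(self, grid):
        doublet = make_band(BandSpec(1620.0, 14.0, 1.0), grid).intensity + \
            make_band(BandSpec(1682.0, 12.0, 0.35), grid).intensity
        assert label_components(doublet[None, :], grid) == \
            [INTERMOLECULAR_LABEL]

    def test_alpha_band_labeled_alpha_helix(self, grid):
        row = make_band(BandSpec(1650.0, 18.0, 1.0), grid).intensity
        assert label_components(row[None, :], grid) == ["alpha-helix"]

    def test_constant_component_labeled_background(self, grid):
        assert label_components(np.ones((1, 51)), grid) == [BACKGROUND_LABEL]

    def test_lone_1620_band_not_intermolecular(self, grid):
        row = make_band(BandSpec(1620.0, 14.0, 1.0), grid).intensity
        labels = label_components(row[None, :], grid)
        assert labels != [INTERMOLECULAR_LABEL]
        assert "beta-sheet(low)" in labels[0]

    def test_labels_invariant_to_rescaling(self, grid):
        rng = np.random.default_rng(11)
        H = rng.random((4, 51)) ** 3
        assert label_components(H, grid) == label_components(7.5 * H, grid)


class TestEvolution:
    def _result_for(self, dataset, W):
        H = np.ones((W.shape[1], 51))
        return NMFResult(W=W, H=H, objective_trace=np.array([1.0]),
                         n_iter=1, converged=True, config=NMFConfig(
                             k=W.shape[1]), labels=["x"] * W.shape[1])

    def test_constant_coefficient_zero_percent_change(self, tiny_cohort):
        _, ds, _ = tiny_cohort
        W = np.ones((len(ds.records), 1))
        evo = component_evolution(self._result_for(ds, W), ds)
        assert evo.percent_change(0, "treated", 0.0, 96.0) == 0.0

    def test_percent_change_matches_direct_formula(self, tiny_cohort):
        _, ds, _ = tiny_cohort
        W = np.ones((len(ds.records), 1))
        for i, rec in enumerate(ds.records):
            if rec.arm == "treated" and rec.time_h == 96.0:
                W[i, 0] = 2.74
        evo = component_evolution(self._result_for(ds, W), ds)
        assert evo.percent_change(0, "treated", 0.0, 96.0) == \
            pytest.approx(174.0)

    def test_missing_time_point_rejected(self, tiny_cohort):
        _, ds, _ = tiny_cohort
        W = np.ones((len(ds.records), 1))
        evo = component_evolution(self._result_for(ds, W), ds)
        with pytest.raises(ParameterError):
            evo.percent_change(0, "treated", 0.0, 55.0)

    def test_quartiles_and_counts_present(self, tiny_cohort):
        _, ds, _ = tiny_cohort
        W = np.random.default_rng(12).random((len(ds.records), 2))
        evo = component_evolution(self._result_for(ds, W), ds)
        sub = evo.table[(evo.table.arm == "treated")
                        & (evo.table.time_h == 0.0)]
        assert set(sub.component) == {0, 1}
        row = sub.iloc[0]
        assert row.q25 <= row.q50 <= row.q75
        assert row.n == 6


class TestTsne:
    def test_separated_blobs_stay_separated(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0.0, 0.05, size=(30, 5))
        b = rng.normal(1.0, 0.05, size=(30, 5))
        W = np.vstack([a, b])
        emb = tsne_embed(W, perplexity=10.0, seed=0)
        from sklearn.metrics import silhouette_score
        labels = np.array([0] * 30 + [1] * 30)
        assert silhouette_score(emb, labels) > 0.5

    def test_same_seed_identical(self):
        W = np.random.default_rng(14).random((30, 5))
        a = tsne_embed(W, perplexity=10.0, seed=3)
        b = tsne_embed(W, perplexity=10.0, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_perplexity_validation(self):
        W = np.random.default_rng(15).random((4, 5))
        with pytest.raises(ParameterError):
            tsne_embed(W, perplexity=30.0, seed=0)
        with pytest.raises(ParameterError):
            tsne_embed(np.vstack([W, W]), perplexity=30.0, seed=0)
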