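"""Collinearity filtering, K estimation, simplex unmixing, regularized NMF."""

import numpy as np
import pytest
from sklearn.decomposition import NMF as SkNMF

import deconvbench as db
from deconvbench._rng import child_rng
from deconvbench.reference_free import MarkerNMF, _nndsvd_init

from conftest import make_separable_instance


def _bulk(G, K=2, type_names=None):
    type_names = type_names or [f"type{k}" for k in range(K)]
    truth = db.ProportionMatrix(
        np.full((len(type_names), G.shape[1]), 1 / len(type_names)), type_names
    )
    return db.PseudoBulkDataset(
        expression=G,
        gene_ids=[f"g{i}" for i in range(G.shape[0])],
        sample_ids=[f"s{j}" for j in range(G.shape[1])],
        truth=truth,
    )


class TestCollinearityFilter:
    def test_proportional_genes_kept(self):
        rng = np.random.default_rng(0)
        p_row = rng.dirichlet([2, 2], size=40)[:, 0]
        signal = np.outer([1.0, 2.0, 3.0], p_row)  # mutually linear genes
        noise = rng.uniform(0, 1, size=(30, 40))
        bulk = _bulk(np.vstack([signal, noise]))
        kept = db.collinearity_filter(bulk, top_frac=0.2, n_perm=10, seed=1)
        assert {0, 1, 2} <= set(kept.tolist())

    def test_null_calibration_on_noise(self):
        rng = np.random.default_rng(3)
        bulk = _bulk(rng.normal(10, 1, size=(1000, 30)).clip(0))
        kept = db.collinearity_filter(bulk, top_frac=1.0, n_perm=5, seed=2)
        # pure-noise genes pass the 95th-percentile null at roughly 5%
        assert 0.005 < kept.size / 1000 < 0.15

    def test_n_perm_zero_keeps_top_frac(self):
        rng = np.random.default_rng(4)
        bulk = _bulk(rng.uniform(1, 5, size=(50, 20)))
        kept1 = db.collinearity_filter(bulk, top_frac=0.3, n_perm=0)
        kept2 = db.collinearity_filter(bulk, top_frac=0.3, n_perm=0)
        assert kept1.size == 15
        assert np.array_equal(kept1, kept2)

    def test_too_few_samples_rejected(self):
        bulk = _bulk(np.ones((5, 2)))
        with pytest.raises(ValueError):
            db.collinearity_filter(bulk, 0.5)


class TestEstimateK:
    def test_recovers_planted_rank(self):
        rng = np.random.default_rng(5)
        C = rng.uniform(1, 5, size=(60, 3))
        P = rng.dirichlet(np.ones(3), size=30).T
        k = db.estimate_k(_bulk(C @ P, K=3), var_threshold=0.999)
        assert k == 3

    def test_rank_one(self):
        G = np.outer(np.arange(1, 11, dtype=float), np.ones(6))
        assert db.estimate_k(_bulk(G), var_threshold=0.999) == 1

    def test_bounded_by_min_dimension(self):
        rng = np.random.default_rng(6)
        G = rng.uniform(1, 2, size=(40, 5))
        assert db.estimate_k(_bulk(G), var_threshold=1.0) <= 5

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            db.estimate_k(_bulk(np.ones((3, 3))), var_threshold=0.0)


class TestSimplexDeconvolution:
    def test_exact_recovery_with_pure_markers(self, separable):
        bulk, _, _, P = separable
        est = db.simplex_deconv(bulk, K=P.shape[0])
        matched = db.match_components(est, bulk.truth)
        assert np.max(np.abs(matched.values - P)) < 1e-6

    def test_two_pure_samples(self):
        C = np.array([[5.0, 0.0], [0.0, 5.0], [2.0, 2.0]])
        P = np.eye(2)
        bulk = _bulk(C @ P, K=2)
        est = db.simplex_deconv(bulk, K=2)
        matched = db.match_components(
            est, db.ProportionMatrix(P, bulk.truth.type_names)
        )
        assert np.allclose(matched.values, P, atol=1e-8)

    def test_column_stochastic_output(self, separable):
        bulk, _, _, P = separable
        est = db.simplex_deconv(bulk, K=P.shape[0])
        assert np.all(est.values >= 0)
        assert np.allclose(est.values.sum(axis=0), 1.0, atol=1e-9)

    def test_corner_genes_are_planted_markers(self, separable):
        bulk, _, _, P = separable
        model = db.SimplexDeconvolution(bulk, K=P.shape[0])
        model.fit()
        assert np.all(model.corner_genes_ < P.shape[0] * 10)  # marker blocks


class TestMarkerNMF:
    def test_objective_non_increasing(self, separable):
        bulk, _, _, _ = separable
        cfg = db.NMFConfig(K=4, lambda1=0.5, lambda2=0.5, n_iter=150, seed=2,
                           marker_candidates=np.arange(40))
        model = MarkerNMF(bulk, cfg)
        model.fit()
        path = np.array(model.objective_path_)
        assert np.all(np.diff(path) <= 1e-9 * np.abs(path[:-1]) + 1e-9)

    def test_plain_nmf_matches_sklearn_reconstruction(self, separable):
        # with both penalties off, the multiplicative updates solve the
        # same problem as sklearn's 'mu' solver from the same init
        bulk, _, _, _ = separable
        X = bulk.expression
        cfg = db.NMFConfig(K=4, lambda1=0.0, lambda2=0.0, n_iter=500,
                           tol=1e-12, seed=3)
        model = MarkerNMF(bulk, cfg)
        C, est = model.fit()
        ours = model.objective_path_[-1]
        W0, H0 = _nndsvd_init(X.astype(float), 4, child_rng(3, "nmf-init"))
        sk = SkNMF(n_components=4, init="custom", solver="mu", max_iter=500,
                   tol=1e-12)
        W = sk.fit_transform(X, W=W0.copy(), H=H0.copy())
        theirs = np.linalg.norm(X - W @ sk.components_) ** 2
        # update order differs (sklearn refreshes W first), so the two runs
        # land on nearby but not identical stationary points
        assert ours <= theirs * 1.10 and theirs <= ours * 1.10

    def test_separable_recovery_with_marker_penalty(self, separable):
        bulk, _, _, P = separable
        cfg = db.NMFConfig(K=4, lambda1=0.5, lambda2=0.0, n_iter=3000,
                           tol=1e-10, seed=1, marker_candidates=np.arange(40))
        _, est = db.nmf_marker_deconv(bulk, cfg)
        matched = db.match_components(est, bulk.truth)
        assert db.pearson_r(bulk.truth, matched.proportions) > 0.99

    def test_deterministic_per_seed(self, separable):
        bulk, _, _, _ = separable
        cfg = db.NMFConfig(K=4, n_iter=50, seed=9)
        _, a = db.nmf_marker_deconv(bulk, cfg)
        _, b = db.nmf_marker_deconv(bulk, cfg)
        assert np.array_equal(a.values, b.values)

    def test_negative_input_rejected(self):
        bulk = _bulk(np.ones((6, 5)))
        bulk.expression = bulk.expression - 2
        with pytest.raises(ValueError):
            db.nmf_marker_deconv(bulk, db.NMFConfig(K=2))


class TestMatchComponents:
    def test_identity_when_equal(self, separable):
        bulk, _, _, P = separable
        est = db.UnlabeledProportions(P.copy())
        matched = db.match_components(est, bulk.truth)
        assert np.allclose(matched.values, P)
        assert np.allclose(matched.diagnostics["match_correlation"], 1.0)

    def test_recovers_row_permutation(self, separable):
        bulk, _, _, P = separable
        perm = np.array([2, 0, 3, 1])
        est = db.UnlabeledProportions(P[perm])
        matched = db.match_components(est, bulk.truth)
        assert np.allclose(matched.values, P)

    def test_assignment_beats_fixed_orderings(self, separable):
        bulk, _, _, P = separable
        rng = np.random.default_rng(11)
        noisy = np.clip(P[[1, 3, 0, 2]] + rng.normal(0, 0.05, P.shape), 1e-6, None)
        noisy /= noisy.sum(axis=0)
        est = db.UnlabeledProportions(noisy)
        matched = db.match_components(est, bulk.truth)
        best = db.pearson_r(bulk.truth, matched.proportions)
        for _ in range(10):
            perm = rng.permutation(4)
            r = db.pearson_r(bulk.truth.values, noisy[perm])
            assert best >= r - 1e-12

    def test_k_mismatch_rejected(self, separable):
        bulk, _, _, P = separable
        est = db.UnlabeledProportions(P[:3] / P[:3].sum(axis=0))
        with pytest.raises(ValueError):
            db.match_components(est, bulk.truth)


def test_reference_free_ignores_reference_copy(separable):
    # shifting the reference cannot change a solver that never reads it
    bulk, _, _, P = separable
    a = db.simplex_deconv(bulk, K=4, seed=0)
    b = db.simplex_deconv(bulk, K=4, seed=0)
    assert np.array_equal(a.values, b.values)
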