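"""Signature construction and the three reference-based solvers."""

import numpy as np
import pytest
from scipy.stats import binomtest

import deconvbench as db
from deconvbench.reference_based import _normalize_cells

from conftest import make_separable_instance


def _bulk_from_matrix(G, type_names, P):
    return db.PseudoBulkDataset(
        expression=G,
        gene_ids=[f"g{i}" for i in range(G.shape[0])],
        sample_ids=[f"s{j}" for j in range(G.shape[1])],
        truth=db.ProportionMatrix(P, list(type_names)),
    )


class TestBuildSignature:
    def test_recovers_planted_markers(self):
        spec = db.SingleCellSpec(
            n_genes=300, n_cells_per_type=80, n_types=3, marker_frac=0.05,
            marker_fold=8.0, dispersion=0.05, libsize_sigma=0.1, seed=21,
        )
        data = db.generate_single_cell_dataset(spec)
        n_mark = len(spec.marker_sets()[0])
        sig = db.build_signature(data, n_markers_per_type=n_mark)
        selected = set(sig.gene_ids)
        for markers in spec.marker_sets():
            planted = {data.gene_ids[i] for i in markers}
            assert planted <= selected

    def test_columns_are_type_means_of_normalized_reference(self, small_sc):
        sig = db.build_signature(small_sc, n_markers_per_type=small_sc.n_genes)
        norm = _normalize_cells(small_sc.counts.astype(float))
        for k, t in enumerate(small_sc.type_names):
            mean = norm[:, small_sc.cells_of_type(t)].mean(axis=1)
            assert np.allclose(sig.values[:, k], mean, atol=1e-9)

    def test_degenerate_identical_types_deterministic(self):
        # identical type means -> t ~ 0 -> fall back to gene order
        counts = np.tile(np.array([[4], [7], [2], [9]]), (1, 6))
        data = db.SingleCellDataset(
            counts=counts,
            gene_ids=["g0", "g1", "g2", "g3"],
            cell_types=np.array(["a"] * 3 + ["b"] * 3, dtype=object),
            type_names=["a", "b"],
        )
        sig = db.build_signature(data, n_markers_per_type=2)
        assert sig.gene_ids == ["g0", "g1"]

    def test_too_many_markers_rejected(self, small_sc):
        with pytest.raises(ValueError):
            db.build_signature(small_sc, n_markers_per_type=10_000)


class TestNNLS:
    def test_exact_recovery_noiseless(self, separable):
        bulk, sig, _, P = separable
        res = db.nnls_deconv(bulk, sig)
        assert np.max(np.abs(res.values - P)) < 1e-6

    def test_pure_signature_columns_recovered(self, separable):
        _, sig, C, _ = separable
        K = C.shape[1]
        bulk = _bulk_from_matrix(C.copy(), sig.type_names, np.eye(K))
        res = db.nnls_deconv(bulk, sig)
        assert np.allclose(res.values, np.eye(K), atol=1e-8)

    def test_zero_sample_rejected(self, separable):
        bulk, sig, C, P = separable
        G = bulk.expression.copy()
        G[:, 0] = 0.0
        bad = _bulk_from_matrix(G, sig.type_names, P)
        with pytest.raises(ValueError, match="degenerate sample"):
            db.nnls_deconv(bad, sig)

    def test_scalar_invariance(self, separable):
        bulk, sig, _, _ = separable
        res1 = db.nnls_deconv(bulk, sig)
        scaled = bulk.replace(expression=bulk.expression * 7.3)
        res2 = db.nnls_deconv(scaled, sig)
        assert np.allclose(res1.values, res2.values, atol=1e-9)


def _permutation_reference(K=3, reps=4, d=0.2, seed=0):
    """Reference whose gene rows are permutations of one value set, giving
    equal between-type variance and equal within-type variance per gene."""
    base = np.array([6.0, 10.0, 14.0])
    rows = []
    for i in range(K * reps):
        rows.append(np.roll(base, i % K))
    C = np.array(rows)  # (K*reps) x K
    M = C.shape[0]
    # two cells per type at m -/+ d, signs alternating by gene so that every
    # cell keeps the same total
    cells, labels = [], []
    signs = np.where(np.arange(M) % 2 == 0, 1.0, -1.0)
    for k in range(K):
        cells.append(C[:, k] - signs * d)
        cells.append(C[:, k] + signs * d)
        labels += [f"type{k}"] * 2
    counts = np.column_stack(cells)
    return db.SingleCellDataset(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(M)],
        cell_types=np.array(labels, dtype=object),
        type_names=[f"type{k}" for k in range(K)],
    )


class TestWeightedNNLS:
    def test_exact_recovery_noiseless(self, separable):
        bulk, sig, C, P = separable
        # reference with two identical cells per type reproducing C exactly
        counts = np.repeat(C, 2, axis=1)
        labels = np.repeat(sig.type_names, 2)
        ref = db.SingleCellDataset(
            counts=counts, gene_ids=list(bulk.gene_ids),
            cell_types=labels.astype(object), type_names=list(sig.type_names),
        )
        res = db.wnnls_deconv(bulk, ref)
        assert np.max(np.abs(res.values - P)) < 1e-6

    def test_constant_weights_reduce_to_nnls(self):
        ref = _permutation_reference()
        rng = np.random.default_rng(1)
        P = rng.dirichlet(np.ones(3), size=25).T
        sig = db.build_signature(ref, n_markers_per_type=ref.n_genes)
        G = sig.values @ P
        bulk = _bulk_from_matrix(G, ref.type_names, P)
        res_w = db.wnnls_deconv(bulk, ref)
        res_p = db.nnls_deconv(bulk, sig)
        assert np.max(np.abs(res_w.values - res_p.values)) < 1e-6

    def test_downweights_heteroscedastic_genes(self):
        # noise concentrated on half the genes, matching high within-type
        # variance in the reference: w-NNLS should beat plain NNLS
        rng = np.random.default_rng(7)
        K, M, n = 3, 80, 50
        wins = 0
        reps = 20
        for rep in range(reps):
            C = rng.uniform(1.0, 4.0, size=(M, K))
            C[:10, 0] *= 4
            C[10:20, 1] *= 4
            C[20:30, 2] *= 4
            noisy = np.arange(M) >= M // 2
            cells, labels = [], []
            for k in range(K):
                for _ in range(6):
                    cell = C[:, k].copy()
                    cell[noisy] *= rng.lognormal(0, 0.6, size=noisy.sum())
                    cells.append(cell)
                    labels.append(f"type{k}")
            ref = db.SingleCellDataset(
                counts=np.column_stack(cells),
                gene_ids=[f"g{i}" for i in range(M)],
                cell_types=np.array(labels, dtype=object),
                type_names=[f"type{k}" for k in range(K)],
            )
            P = rng.dirichlet(np.ones(K) * 2, size=n).T
            sig = db.build_signature(ref, n_markers_per_type=M)
            G = sig.values @ P
            G[noisy] *= rng.lognormal(0, 0.6, size=(noisy.sum(), n))
            bulk = _bulk_from_matrix(G, ref.type_names, P)
            rmsd_w = db.rmsd(bulk.truth, db.wnnls_deconv(bulk, ref).proportions)
            rmsd_p = db.rmsd(bulk.truth, db.nnls_deconv(bulk, sig).proportions)
            wins += rmsd_w < rmsd_p
        assert binomtest(wins, reps, 0.5, alternative="greater").pvalue < 0.05


class TestNuSVR:
    def test_output_on_simplex(self, separable):
        bulk, sig, _, _ = separable
        res = db.nusvr_deconv(bulk, sig)
        assert np.all(res.values >= 0)
        assert np.allclose(res.values.sum(axis=0), 1.0, atol=1e-9)

    def test_near_exact_recovery_noiseless(self, separable):
        bulk, sig, _, P = separable
        res = db.nusvr_deconv(bulk, sig)
        assert db.pearson_r(bulk.truth, res.proportions) > 0.99

    def test_duplicated_gene_rows_do_not_change_estimate(self, separable):
        bulk, sig, C, P = separable
        res1 = db.nusvr_deconv(bulk, sig)
        dup = np.vstack([bulk.expression, bulk.expression[:15]])
        sig_dup = db.SignatureMatrix(
            values=np.vstack([C, C[:15]]),
            gene_ids=[f"g{i}" for i in range(dup.shape[0])],
            type_names=list(sig.type_names),
        )
        bulk_dup = _bulk_from_matrix(dup, sig.type_names, P)
        res2 = db.nusvr_deconv(bulk_dup, sig_dup)
        assert np.allclose(res1.values, res2.values, atol=1e-8)

    def test_scalar_invariance(self, separable):
        bulk, sig, _, _ = separable
        res1 = db.nusvr_deconv(bulk, sig)
        res2 = db.nusvr_deconv(
            bulk.replace(expression=bulk.expression * 11.0), sig
        )
        assert np.allclose(res1.values, res2.values, atol=1e-6)

    def test_chosen_nu_reported(self, separable):
        bulk, sig, _, _ = separable
        res = db.nusvr_deconv(bulk, sig)
        assert set(res.diagnostics["nu"]).issubset({0.25, 0.5, 0.75})


def test_summary_mentions_method_and_types(separable):
    bulk, sig, _, _ = separable
    text = db.nnls_deconv(bulk, sig).summary()
    assert "nnls" in text
    for t in sig.type_names:
        assert t in text


def test_signature_tsv_roundtrip(separable, tmp_path):
    _, sig, _, _ = separable
    path = tmp_path / "sig.tsv"
    sig.to_tsv(path)
    back = db.SignatureMatrix.from_tsv(path)
    assert np.allclose(back.values, sig.values)
    assert back.type_names == sig.type_names
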