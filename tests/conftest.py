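import numpy as np
import pytest

import deconvbench as db


@pytest.fixture(scope="session")
def small_sc() -> db.SingleCellDataset:
    """A small 3-type synthetic cell pool shared across read-only tests."""
    spec = db.SingleCellSpec(
        n_genes=200, n_cells_per_type=30, n_types=3, marker_frac=0.05,
        marker_fold=5.0, dispersion=0.3, libsize_sigma=0.3, seed=11,
    )
    return db.generate_single_cell_dataset(spec)


def make_separable_instance(K=4, M=120, n=50, seed=0, markers_per_type=10, pure=True):
    """Noiseless separable mixture G = C P with planted marker blocks.

    Marker genes of type k occupy rows [k*mpt, (k+1)*mpt) and are expressed
    only in type k when ``pure``; remaining rows are dense random profiles.
    """
    rng = np.random.default_rng(seed)
    C = rng.uniform(0.5, 2.0, size=(M, K))
    for k in range(K):
        rows = slice(k * markers_per_type, (k + 1) * markers_per_type)
        C[rows, :] = 0.0 if pure else 0.01
        C[rows, k] = 5.0
    # equal per-type column totals (equal mRNA content per cell), so
    # normalization-based solvers can recover proportions exactly
    C *= C.sum(axis=0).mean() / C.sum(axis=0, keepdims=True)
    P = rng.dirichlet(np.ones(K) * 2, size=n).T
    type_names = [f"type{k}" for k in range(K)]
    truth = db.ProportionMatrix(P, type_names)
    bulk = db.PseudoBulkDataset(
        expression=C @ P,
        gene_ids=[f"g{i}" for i in range(M)],
        sample_ids=[f"s{j}" for j in range(n)],
        truth=truth,
    )
    sig = db.SignatureMatrix(values=C, gene_ids=list(bulk.gene_ids), type_names=type_names)
    return bulk, sig, C, P


@pytest.fixture(scope="session")
def separable():
    return make_separable_instance()
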