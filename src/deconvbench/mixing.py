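"""Ideal mixing of single cells into pseudo-bulk RNA-seq samples.

For each bulk sample j with target composition P[:, j], cell-type counts
are drawn from a multinomial over ``cells_per_sample`` cells; that many
cells are sampled with replacement from each type's pool and their count
vectors summed to form column j of G. The realized multinomial fractions
are the exact composition of the constructed sample and serve as the
default ground truth (the intended Dirichlet draw is kept alongside).

Standard bulk post-processing follows the benchmark's recipe: drop genes
with fewer than ``min_count`` reads in at least ``sample_frac`` of samples,
then rescale each column to a fixed total (counts-per-million by default).
"""

from __future__ import annotations

import numpy as np

from ._rng import child_rng
from .datasets import ProportionMatrix, PseudoBulkDataset, SingleCellDataset

__all__ = ["ideal_mix", "filter_genes", "column_normalize", "mixing_noise_profile"]


def ideal_mix(
    data: SingleCellDataset,
    P: ProportionMatrix,
    cells_per_sample: int = 500,
    seed: int = 0,
) -> PseudoBulkDataset:
    """Sum randomly sampled single cells into pseudo-bulk columns.

    ``truth`` holds the realized multinomial fractions; ``intended`` the
    Dirichlet target columns. Deterministic per seed.
    """
    if cells_per_sample < 1:
        raise ValueError("cells_per_sample must be >= 1")
    if P.n_samples == 0:
        raise ValueError("empty proportion matrix")
    missing = [t for t in P.type_names if t not in data.type_names]
    if missing:
        raise ValueError(f"types absent from single-cell data: {missing}")

    pools = {t: data.cells_of_type(t) for t in P.type_names}
    rng = child_rng(seed, "ideal-mix")
    n = P.n_samples
    expr = np.zeros((data.n_genes, n), dtype=np.int64)
    realized = np.zeros((P.n_types, n))
    for j in range(n):
        counts = rng.multinomial(cells_per_sample, P.values[:, j])
        for k, t in enumerate(P.type_names):
            if counts[k] == 0:
                continue
            chosen = rng.choice(pools[t], size=counts[k], replace=True)
            expr[:, j] += data.counts[:, chosen].sum(axis=1).astype(np.int64)
        realized[:, j] = counts / cells_per_sample
    return PseudoBulkDataset(
        expression=expr,
        gene_ids=list(data.gene_ids),
        sample_ids=[f"sample{j}" for j in range(n)],
        truth=ProportionMatrix(realized, list(P.type_names)),
        intended=P,
    )


def filter_genes(
    bulk: PseudoBulkDataset, min_count: float = 10, sample_frac: float = 0.8
) -> PseudoBulkDataset:
    """Drop genes lowly expressed in most samples.

    Gene g is removed iff the number of samples where its count is strictly
    below ``min_count`` is at least ``sample_frac`` of all samples. Gene
    order is otherwise preserved; idempotent.
    """
    n = bulk.n_samples
    low = (bulk.expression < min_count).sum(axis=1)
    keep = low < sample_frac * n
    if not keep.any():
        raise ValueError("gene filter removed all genes")
    return bulk.replace(
        expression=bulk.expression[keep],
        gene_ids=[g for g, k in zip(bulk.gene_ids, keep) if k],
    )


def column_normalize(bulk: PseudoBulkDataset, scale: float = 1e6) -> PseudoBulkDataset:
    """Rescale every sample column to total ``scale`` (CPM by default)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = bulk.expression.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("cannot normalize a zero-total column")
    return bulk.replace(expression=bulk.expression * (scale / totals)[None, :])


def mixing_noise_profile(
    bulk: PseudoBulkDataset,
    data: SingleCellDataset,
    cells_per_sample: int,
) -> np.ndarray:
    """Per-gene mean residual of G around its ideal-mixing expectation.

    Under ideal mixing the conditional expectation of column j given the
    realized type counts is ``C_mean @ (truth[:, j] * cells_per_sample)``
    with ``C_mean`` the per-type mean profile of the cell pool; the mixing
    error has mean zero. Returns the residual averaged over samples, for
    diagnostics only.
    """
    type_names = bulk.truth.type_names
    if bulk.expression.shape[0] != data.n_genes:
        raise ValueError("bulk/reference gene dimension mismatch")
    c_mean = np.column_stack(
        [data.counts[:, data.cells_of_type(t)].mean(axis=1) for t in type_names]
    )
    expected = c_mean @ (bulk.truth.values * cells_per_sample)
    return (bulk.expression - expected).mean(axis=1)
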