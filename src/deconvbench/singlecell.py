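"""Synthetic single-cell count data with planted marker structure.

The generator emulates the statistical shape of real cell-level expression
datasets used to build pseudo-bulk tissues: K cell types, each with a set of
marker genes whose mean expression is elevated ``marker_fold``-fold in the
owning type, negative-binomial count noise with tunable overdispersion, and
log-normal per-cell library-size variation. Marker gene sets are disjoint
across types, so reference-free "solvability" assumptions hold by
construction and can be switched off by sending ``marker_fold`` to 1.

Two controlled discrepancy operators act on a dataset copy:

* :func:`reduce_variability` shrinks every cell toward its type mean,
  emulating simulator-generated references that are much less variable than
  real data.
* :func:`platform_shift` applies one multiplicative log-normal bias per gene
  (shared across cells) plus extra dropout, emulating platform or assay
  differences such as scRNA-seq versus snRNA-seq references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import child_rng
from .datasets import SingleCellDataset

__all__ = [
    "SingleCellSpec",
    "generate_single_cell_dataset",
    "reduce_variability",
    "platform_shift",
]


@dataclass
class SingleCellSpec:
    """Parameters of the synthetic cell-level generator.

    Parameters
    ----------
    n_genes : int
        Number of genes.
    n_cells_per_type : int or sequence of int
        Cells per type (scalar broadcast to all K types).
    n_types : int
        Number of cell types K.
    marker_frac : float
        Fraction of genes designated markers of each type; the K marker
        sets are disjoint, so ``marker_frac * n_types`` must be <= 1.
    marker_fold : float
        Multiplicative elevation of a marker gene in its own type (> 1).
    base_mean : float
        Scale of the per-gene baseline mean expression.
    gene_sigma : float
        Log-normal spread of per-gene baselines around ``base_mean``;
        0 makes every baseline exactly ``base_mean``.
    dispersion : float
        Negative-binomial dispersion (variance = m + dispersion * m**2);
        0 gives Poisson counts.
    libsize_sigma : float
        Log-normal sigma of the per-cell library-size factor (mean 1).
    seed : int
        Master seed for the generator.
    """

    n_genes: int
    n_cells_per_type: int | list[int]
    n_types: int
    marker_frac: float = 0.05
    marker_fold: float = 5.0
    base_mean: float = 5.0
    gene_sigma: float = 0.6
    dispersion: float = 0.3
    libsize_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_types <= 0:
            raise ValueError("n_genes and n_types must be positive")
        if np.isscalar(self.n_cells_per_type):
            self.n_cells_per_type = [int(self.n_cells_per_type)] * self.n_types
        self.n_cells_per_type = [int(c) for c in self.n_cells_per_type]
        if len(self.n_cells_per_type) != self.n_types:
            raise ValueError("n_cells_per_type length must equal n_types")
        if any(c <= 0 for c in self.n_cells_per_type):
            raise ValueError("n_cells_per_type must be positive")
        if self.marker_frac < 0 or self.marker_frac * self.n_types > 1:
            raise ValueError(
                "marker_frac * n_types must be <= 1 (marker sets are disjoint)"
            )
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must be > 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.libsize_sigma < 0 or self.gene_sigma < 0:
            raise ValueError("sigmas must be >= 0")

    @property
    def type_names(self) -> list[str]:
        return [f"type{k}" for k in range(self.n_types)]

    def marker_sets(self) -> list[np.ndarray]:
        """Disjoint marker gene index blocks, one per type."""
        n_mark = int(round(self.marker_frac * self.n_genes))
        return [
            np.arange(k * n_mark, (k + 1) * n_mark) for k in range(self.n_types)
        ]


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with variance m + dispersion*m**2 (Poisson at 0)."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_single_cell_dataset(spec: SingleCellSpec) -> SingleCellDataset:
    """Draw a synthetic :class:`SingleCellDataset` from ``spec``.

    Per-gene baseline means are log-normal around ``base_mean``; each type's
    markers have that baseline multiplied by ``marker_fold`` in the owning
    type only. Counts are negative-binomial around the type mean scaled by
    a per-cell log-normal library factor. Deterministic per seed.
    """
    rng_base = child_rng(spec.seed, "baseline")
    rng_counts = child_rng(spec.seed, "counts")
    rng_lib = child_rng(spec.seed, "libsize")

    if spec.gene_sigma > 0:
        baseline = spec.base_mean * rng_base.lognormal(
            -0.5 * spec.gene_sigma**2, spec.gene_sigma, size=spec.n_genes
        )
    else:
        baseline = np.full(spec.n_genes, float(spec.base_mean))

    # genes x K expected means
    mean_by_type = np.tile(baseline[:, None], (1, spec.n_types))
    for k, markers in enumerate(spec.marker_sets()):
        mean_by_type[markers, k] *= spec.marker_fold

    blocks = []
    labels = []
    for k, name in enumerate(spec.type_names):
        n_k = spec.n_cells_per_type[k]
        if spec.libsize_sigma > 0:
            lib = rng_lib.lognormal(
                -0.5 * spec.libsize_sigma**2, spec.libsize_sigma, size=n_k
            )
        else:
            lib = np.ones(n_k)
        mu = mean_by_type[:, [k]] * lib[None, :]
        blocks.append(_nb_sample(rng_counts, mu, spec.dispersion))
        labels.extend([name] * n_k)

    return SingleCellDataset(
        counts=np.concatenate(blocks, axis=1).astype(np.int64),
        gene_ids=[f"g{i}" for i in range(spec.n_genes)],
        cell_types=np.array(labels, dtype=object),
        type_names=spec.type_names,
    )


def reduce_variability(
    data: SingleCellDataset, shrink: float, seed: int = 0
) -> SingleCellDataset:
    """Pull every cell toward its cell-type mean profile by factor ``shrink``.

    ``shrink=0`` is the identity; ``shrink=1`` collapses each type to its
    (rounded) mean profile. Values are re-rounded to non-negative integers
    with banker's rounding; labels are preserved. Per-type mean profiles are
    preserved up to rounding. ``seed`` is accepted for interface symmetry
    with the other discrepancy operators; the operation is deterministic.
    """
    if not 0 <= shrink <= 1:
        raise ValueError("shrink must lie in [0, 1]")
    if shrink == 0:
        return data.replace(counts=data.counts.copy())
    new = np.asarray(data.counts, dtype=float).copy()
    for t in data.type_names:
        idx = data.cells_of_type(t)
        mean = new[:, idx].mean(axis=1, keepdims=True)
        new[:, idx] += shrink * (mean - new[:, idx])
    new = np.clip(np.rint(new), 0, None).astype(np.int64)
    return data.replace(counts=new)


def platform_shift(
    data: SingleCellDataset,
    bias_sigma: float,
    dropout_delta: float = 0.0,
    seed: int = 0,
) -> SingleCellDataset:
    """Apply a per-gene platform bias plus extra dropout.

    Each gene receives one multiplicative bias factor exp(N(0, bias_sigma))
    shared across all cells, then a fraction ``dropout_delta`` of its
    nonzero entries is zeroed. Zeros never become nonzero. Deterministic
    per seed.
    """
    if bias_sigma < 0:
        raise ValueError("bias_sigma must be >= 0")
    if not 0 <= dropout_delta < 1:
        raise ValueError("dropout_delta must lie in [0, 1)")
    counts = np.asarray(data.counts, dtype=float).copy()
    if bias_sigma > 0:
        rng_bias = child_rng(seed, "platform-bias")
        bias = np.exp(rng_bias.normal(0.0, bias_sigma, size=data.n_genes))
        counts *= bias[:, None]
    if dropout_delta > 0:
        rng_drop = child_rng(seed, "platform-dropout")
        for g in range(data.n_genes):
            nz = np.flatnonzero(counts[g] > 0)
            n_drop = int(np.floor(dropout_delta * nz.size))
            if n_drop:
                counts[g, rng_drop.choice(nz, size=n_drop, replace=False)] = 0
    counts = np.clip(np.rint(counts), 0, None).astype(np.int64)
    return data.replace(counts=counts)
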