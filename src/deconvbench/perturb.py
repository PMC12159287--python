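"""Controlled manipulations of the bulk-generating cell-level data.

Three operators introduce systematic discrepancies between the cells that
compose the pseudo-bulk and the pristine copy later used as reference:

* :func:`mean_shift` — add a fraction of each gene's within-type mean to
  every cell (fractions 0.1 / 0.3 / 0.5 / 0.7 in the benchmark grid);
* :func:`truncate_cells` — remove the top or bottom 10% of cells per type,
  ranked by total counts;
* :func:`scale_expression` — multiply all expression by a global factor
  (0.4 / 0.8 / 1.2 / 1.8 in the grid). Global scaling is absorbed by
  downstream column normalization, so it is expected to be inert.

All operators keep data count-valued: mean_shift and scale_expression round
half-up (floor(x + 0.5)) to the nearest non-negative integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SingleCellDataset

__all__ = [
    "PerturbationSpec",
    "mean_shift",
    "truncate_cells",
    "scale_expression",
    "apply_perturbation",
    "MEAN_SHIFT_GRID",
    "FACTOR_GRID",
]

MEAN_SHIFT_GRID = (0.1, 0.3, 0.5, 0.7)
FACTOR_GRID = (0.4, 0.8, 1.2, 1.8)


@dataclass
class PerturbationSpec:
    """Declarative description of one manipulation."""

    kind: str  # mean_shift | truncate | factor
    fraction: float = 0.0  # mean_shift
    side: str = "top"  # truncate
    q: float = 0.1  # truncate
    factor: float = 1.0  # factor

    def __post_init__(self) -> None:
        if self.kind not in {"mean_shift", "truncate", "factor"}:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.fraction < 0:
            raise ValueError("fraction must be >= 0")
        if not 0 <= self.q <= 0.5:
            raise ValueError("q must lie in [0, 0.5]")
        if self.factor <= 0:
            raise ValueError("factor must be positive")
        if self.side not in {"top", "bottom"}:
            raise ValueError("side must be 'top' or 'bottom'")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(x + 0.5), 0, None).astype(np.int64)


def mean_shift(data: SingleCellDataset, fraction: float) -> SingleCellDataset:
    """Add ``fraction`` of the within-type mean of each gene to every cell."""
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    if fraction == 0:
        return data.replace(counts=data.counts.copy())
    new = np.asarray(data.counts, dtype=float).copy()
    for t in data.type_names:
        idx = data.cells_of_type(t)
        mean = new[:, idx].mean(axis=1, keepdims=True)
        new[:, idx] += fraction * mean
    return data.replace(counts=_round_half_up(new))


def truncate_cells(
    data: SingleCellDataset, side: str, q: float = 0.1
) -> SingleCellDataset:
    """Remove floor(q * n_k) cells per type from the stated expression extreme.

    Cells are ranked by total counts within each type; the remaining cells
    keep their original order. Every type must retain at least one cell.
    """
    if side not in {"top", "bottom"}:
        raise ValueError("side must be 'top' or 'bottom'")
    if not 0 <= q <= 0.5:
        raise ValueError("q must lie in [0, 0.5]")
    totals = data.counts.sum(axis=0)
    drop: set[int] = set()
    for t in data.type_names:
        idx = data.cells_of_type(t)
        n_remove = int(np.floor(q * idx.size))
        if n_remove >= idx.size:
            raise ValueError(f"truncation would empty type {t!r}")
        if n_remove == 0:
            continue
        order = idx[np.argsort(totals[idx], kind="stable")]
        victims = order[-n_remove:] if side == "top" else order[:n_remove]
        drop.update(victims.tolist())
    keep = np.array([i for i in range(data.n_cells) if i not in drop])
    return data.replace(
        counts=data.counts[:, keep], cell_types=data.cell_types[keep]
    )


def scale_expression(data: SingleCellDataset, factor: float) -> SingleCellDataset:
    """Multiply every entry by ``factor`` (rounded half-up to integers)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    if factor == 1:
        return data.replace(counts=data.counts.copy())
    return data.replace(counts=_round_half_up(data.counts * float(factor)))


def apply_perturbation(data: SingleCellDataset, spec: PerturbationSpec) -> SingleCellDataset:
    if spec.kind == "mean_shift":
        return mean_shift(data, spec.fraction)
    if spec.kind == "truncate":
        return truncate_cells(data, spec.side, spec.q)
    return scale_expression(data, spec.factor)
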