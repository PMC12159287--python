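"""Core data containers and their plain-text readers/writers.

The containers mirror the linear mixing model G = C P + eps used throughout
the package:

* :class:`SingleCellDataset` — genes x cells counts with per-cell type
  labels; the cell-level profiles that populate C and that pseudo-bulk
  samples are summed from.
* :class:`ProportionMatrix` — K x n column-stochastic matrix P of cell-type
  fractions.
* :class:`PseudoBulkDataset` — genes x samples bulk matrix G together with
  the realized (and intended) ground-truth proportions.
* :class:`SignatureMatrix` — genes x K expected per-type expression C over a
  discriminative gene subset.

All matrices are dense numpy arrays; I/O is TSV (and MatrixMarket for the
single-cell counts) so every artifact is plain text.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite

__all__ = [
    "SingleCellDataset",
    "ProportionMatrix",
    "PseudoBulkDataset",
    "SignatureMatrix",
]

_SIMPLEX_TOL = 1e-9


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} must be unique")


@dataclass
class SingleCellDataset:
    """Genes x cells non-negative count matrix with cell-type labels."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_types: np.ndarray  # per-cell label, dtype object/str
    type_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.cell_types = np.asarray(self.cell_types)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be non-negative and finite")
        if self.counts.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length mismatch")
        if self.counts.shape[1] != len(self.cell_types):
            raise ValueError("cell_types length mismatch")
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.type_names, "type_names")
        present = set(self.cell_types.tolist())
        missing = [t for t in self.type_names if t not in present]
        if missing:
            raise ValueError(f"types with no cells: {missing}")
        stray = present - set(self.type_names)
        if stray:
            raise ValueError(f"labels not in type_names: {sorted(stray)}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def cells_of_type(self, type_name: str) -> np.ndarray:
        """Column indices of cells carrying ``type_name``."""
        return np.flatnonzero(self.cell_types == type_name)

    def type_mean_profiles(self) -> np.ndarray:
        """Genes x K matrix of per-type mean count profiles."""
        return np.column_stack(
            [self.counts[:, self.cells_of_type(t)].mean(axis=1) for t in self.type_names]
        )

    def replace(self, **kwargs) -> "SingleCellDataset":
        return dataclasses.replace(self, **kwargs)

    # ---- I/O -------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write counts as TSV (gene rows, cell columns) plus a labels sidecar."""
        path = Path(path)
        cells = [f"cell{i}" for i in range(self.n_cells)]
        pd.DataFrame(self.counts, index=self.gene_ids, columns=cells).to_csv(
            path, sep="\t", index_label="gene"
        )
        pd.DataFrame({"cell": cells, "cell_type": self.cell_types}).to_csv(
            path.with_suffix(path.suffix + ".labels"), sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SingleCellDataset":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = pd.read_csv(path.with_suffix(path.suffix + ".labels"), sep="\t")
        types = list(dict.fromkeys(labels["cell_type"]))
        return cls(
            counts=df.to_numpy(),
            gene_ids=[str(g) for g in df.index],
            cell_types=labels["cell_type"].to_numpy(),
            type_names=types,
        )

    def to_mtx(self, path: str | Path) -> None:
        """Write counts as MatrixMarket with gene/label TSV sidecars."""
        path = Path(path)
        from scipy.sparse import csr_matrix

        mmwrite(str(path), csr_matrix(self.counts))
        base = path.with_suffix("")
        pd.Series(self.gene_ids, name="gene").to_csv(
            base.with_suffix(".genes.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            {"cell": [f"cell{i}" for i in range(self.n_cells)], "cell_type": self.cell_types}
        ).to_csv(base.with_suffix(".labels.tsv"), sep="\t", index=False)

    @classmethod
    def from_mtx(cls, path: str | Path) -> "SingleCellDataset":
        path = Path(path)
        counts = np.asarray(mmread(str(path)).todense())
        base = path.with_suffix("")
        genes = pd.read_csv(base.with_suffix(".genes.tsv"), sep="\t")["gene"].tolist()
        labels = pd.read_csv(base.with_suffix(".labels.tsv"), sep="\t")
        types = list(dict.fromkeys(labels["cell_type"]))
        return cls(
            counts=counts,
            gene_ids=[str(g) for g in genes],
            cell_types=labels["cell_type"].to_numpy(),
            type_names=types,
        )


@dataclass
class ProportionMatrix:
    """K x n column-stochastic matrix of cell-type proportions."""

    values: np.ndarray
    type_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (types x samples)")
        if len(self.type_names) != self.values.shape[0]:
            raise ValueError("type_names length mismatch")
        if np.any(self.values < -_SIMPLEX_TOL) or np.any(self.values > 1 + _SIMPLEX_TOL):
            raise ValueError("proportions must lie in [0, 1]")
        sums = self.values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("columns must sum to 1")

    @property
    def n_types(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def reorder(self, type_names: Sequence[str]) -> "ProportionMatrix":
        idx = [self.type_names.index(t) for t in type_names]
        return ProportionMatrix(self.values[idx], list(type_names))

    def to_tsv(self, path: str | Path) -> None:
        samples = [f"sample{j}" for j in range(self.n_samples)]
        pd.DataFrame(self.values, index=self.type_names, columns=samples).to_csv(
            path, sep="\t", index_label="cell_type"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProportionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(), type_names=[str(t) for t in df.index])


@dataclass
class PseudoBulkDataset:
    """Genes x samples bulk expression with realized/intended ground truth."""

    expression: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    truth: ProportionMatrix
    intended: ProportionMatrix | None = None

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.ndim != 2:
            raise ValueError("expression must be 2-D (genes x samples)")
        if np.any(self.expression < 0) or not np.all(np.isfinite(self.expression)):
            raise ValueError("expression must be non-negative and finite")
        if self.expression.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length mismatch")
        if self.expression.shape[1] != len(self.sample_ids):
            raise ValueError("sample_ids length mismatch")
        if self.truth.n_samples != self.expression.shape[1]:
            raise ValueError("truth sample count mismatch")
        _check_unique(self.gene_ids, "gene_ids")

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def replace(self, **kwargs) -> "PseudoBulkDataset":
        return dataclasses.replace(self, **kwargs)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(self.expression, index=self.gene_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", index_label="gene"
        )
        self.truth.to_tsv(path.with_suffix(path.suffix + ".truth"))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PseudoBulkDataset":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        truth = ProportionMatrix.from_tsv(path.with_suffix(path.suffix + ".truth"))
        return cls(
            expression=df.to_numpy(),
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            truth=truth,
        )


@dataclass
class SignatureMatrix:
    """Genes x K expected per-type expression over a signature gene subset."""

    values: np.ndarray
    gene_ids: list[str]
    type_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x types)")
        if np.any(self.values < 0):
            raise ValueError("signature must be non-negative")
        if len(self.type_names) < 2:
            raise ValueError("need at least two cell types")
        if self.values.shape != (len(self.gene_ids), len(self.type_names)):
            raise ValueError("shape mismatch with gene_ids/type_names")
        _check_unique(self.gene_ids, "gene_ids")

    @property
    def n_types(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.gene_ids, columns=self.type_names).to_csv(
            path, sep="\t", index_label="gene"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            values=df.to_numpy(),
            gene_ids=[str(g) for g in df.index],
            type_names=[str(t) for t in df.columns],
        )
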