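"""Reference-based deconvolution: signature construction plus three solvers.

Given the mixing model G = C P + eps with C known (built from a cell-level
reference), each solver estimates one composition column per bulk sample:

* :class:`NNLSDeconvolution` — plain non-negative least squares per sample.
* :class:`WeightedNNLSDeconvolution` — w-NNLS with gene weights favouring
  low within-type and high between-type variation, residual variance
  re-estimated iteratively.
* :class:`NuSVRDeconvolution` — linear nu-support-vector regression of each
  (z-scored) sample on the signature columns over a small nu grid.

Each model is built from a pseudo-bulk dataset plus a signature or
reference and its ``fit()`` returns a :class:`~deconvbench.results.DeconvolutionResult`.
The functional wrappers ``nnls_deconv`` / ``wnnls_deconv`` / ``nusvr_deconv``
are one-liners over the classes.
"""

from __future__ import annotations

import warnings as _warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls
from sklearn.svm import NuSVR

from .datasets import ProportionMatrix, PseudoBulkDataset, SignatureMatrix, SingleCellDataset
from .results import DeconvolutionResult

__all__ = [
    "build_signature",
    "NNLSDeconvolution",
    "WeightedNNLSDeconvolution",
    "NuSVRDeconvolution",
    "nnls_deconv",
    "wnnls_deconv",
    "nusvr_deconv",
]

_EPS_REG = 1e-8


def _normalize_cells(counts: np.ndarray, scale: float = 1e6) -> np.ndarray:
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("reference contains zero-total cells")
    return counts * (scale / totals)[None, :]


def build_signature(
    reference: SingleCellDataset, n_markers_per_type: int = 50
) -> SignatureMatrix:
    """Signature matrix from per-type means of the normalized reference.

    Cells are normalized to equal totals (CPM); per-type columns are mean
    profiles. For each type the ``n_markers_per_type`` genes with largest
    Welch t-statistic (type vs rest) are selected; the union of selections
    forms the signature rows. Ties break by gene order.
    """
    if reference.n_types < 2:
        raise ValueError("need at least 2 cell types")
    if n_markers_per_type > reference.n_genes:
        raise ValueError("n_markers_per_type exceeds gene count")
    for t in reference.type_names:
        if reference.cells_of_type(t).size < 2:
            raise ValueError(f"type {t!r} has fewer than 2 cells")

    norm = _normalize_cells(np.asarray(reference.counts, dtype=float))
    means = np.column_stack(
        [norm[:, reference.cells_of_type(t)].mean(axis=1) for t in reference.type_names]
    )

    selected: set[int] = set()
    order = np.arange(reference.n_genes)
    for k, t in enumerate(reference.type_names):
        idx = reference.cells_of_type(t)
        rest = np.setdiff1d(np.arange(reference.n_cells), idx)
        x, y = norm[:, idx], norm[:, rest]
        m1, m2 = x.mean(axis=1), y.mean(axis=1)
        v1 = x.var(axis=1, ddof=1) / idx.size
        v2 = y.var(axis=1, ddof=1) / rest.size
        t_stat = (m1 - m2) / np.sqrt(v1 + v2 + 1e-12)
        # stable sort on (-t, gene order) implements the tie-break
        rank = np.lexsort((order, -t_stat))
        selected.update(rank[:n_markers_per_type].tolist())

    rows = np.array(sorted(selected))
    return SignatureMatrix(
        values=means[rows],
        gene_ids=[reference.gene_ids[i] for i in rows],
        type_names=list(reference.type_names),
    )


def _shared_rows(bulk: PseudoBulkDataset, gene_ids: list[str]):
    pos = {g: i for i, g in enumerate(bulk.gene_ids)}
    sig_rows, bulk_rows = [], []
    for i, g in enumerate(gene_ids):
        if g in pos:
            sig_rows.append(i)
            bulk_rows.append(pos[g])
    if not sig_rows:
        raise ValueError("no shared genes between bulk and signature")
    return np.array(sig_rows), np.array(bulk_rows)


def _finalize(raw: np.ndarray, type_names, method, diagnostics, warns) -> DeconvolutionResult:
    sums = raw.sum(axis=0)
    if np.any(sums <= 0):
        bad = np.flatnonzero(sums <= 0).tolist()
        raise ValueError(f"degenerate sample(s) with all-zero estimate: {bad}")
    return DeconvolutionResult(
        proportions=ProportionMatrix(raw / sums[None, :], list(type_names)),
        method=method,
        diagnostics=diagnostics,
        warnings=warns,
    )


class NNLSDeconvolution:
    """Per-sample non-negative least squares on a known signature."""

    method = "nnls"

    def __init__(self, bulk: PseudoBulkDataset, signature: SignatureMatrix):
        self.bulk = bulk
        self.signature = signature
        sig_rows, bulk_rows = _shared_rows(bulk, signature.gene_ids)
        if sig_rows.size < signature.n_types:
            raise ValueError("fewer shared genes than cell types")
        self.C = signature.values[sig_rows]
        self.G = bulk.expression[bulk_rows]
        if np.linalg.matrix_rank(self.C) < signature.n_types:
            _warnings.warn("signature matrix is rank-deficient on shared genes")

    def fit(self) -> DeconvolutionResult:
        K, n = self.signature.n_types, self.bulk.n_samples
        raw = np.zeros((K, n))
        resid = np.zeros(n)
        for j in range(n):
            g = self.G[:, j]
            if not np.any(g > 0):
                raise ValueError(f"degenerate sample {j}: all-zero expression")
            raw[:, j], resid[j] = _nnls(self.C, g)
        diag = pd.DataFrame({"residual": resid}, index=self.bulk.sample_ids)
        return _finalize(raw, self.signature.type_names, self.method, diag, [])


class WeightedNNLSDeconvolution:
    """Iteratively re-weighted NNLS built from a single-cell reference.

    Gene weights are

        w_g = between-type variance of mean profiles
              / (pooled within-type variance + residual variance + eps)

    so genes that separate types cleanly and fit well dominate the solve.
    Per-gene residual variance (across samples) is re-estimated after each
    pass for ``n_iter`` passes.
    """

    method = "wnnls"

    def __init__(
        self,
        bulk: PseudoBulkDataset,
        reference: SingleCellDataset,
        n_iter: int = 5,
        tol: float = 1e-8,
    ):
        self.bulk = bulk
        self.n_iter = int(n_iter)
        self.tol = tol
        self.type_names = list(reference.type_names)
        norm = _normalize_cells(np.asarray(reference.counts, dtype=float))
        means, wvars = [], []
        for t in reference.type_names:
            idx = reference.cells_of_type(t)
            means.append(norm[:, idx].mean(axis=1))
            wvars.append(norm[:, idx].var(axis=1, ddof=1) if idx.size > 1 else np.zeros(reference.n_genes))
        C_full = np.column_stack(means)
        within_full = np.mean(np.column_stack(wvars), axis=1)

        sig_rows, bulk_rows = _shared_rows(bulk, reference.gene_ids)
        if sig_rows.size < len(self.type_names):
            raise ValueError("fewer shared genes than cell types")
        self.C = C_full[sig_rows]
        self.within = within_full[sig_rows]
        self.between = self.C.var(axis=1, ddof=0)
        self.G = bulk.expression[bulk_rows]

    def fit(self) -> DeconvolutionResult:
        K, n = len(self.type_names), self.bulk.n_samples
        m = self.C.shape[0]
        resid_var = np.zeros(m)
        raw = np.zeros((K, n))
        prev = None
        converged = False
        for _ in range(self.n_iter):
            w = self.between / (self.within + resid_var + _EPS_REG)
            sw = np.sqrt(w)[:, None]
            Cw = self.C * sw
            for j in range(n):
                g = self.G[:, j]
                if not np.any(g > 0):
                    raise ValueError(f"degenerate sample {j}: all-zero expression")
                raw[:, j], _ = _nnls(Cw, g * sw[:, 0])
            resid = self.G - self.C @ raw
            resid_var = np.mean(resid**2, axis=1)
            if prev is not None and np.max(np.abs(raw - prev)) < self.tol * max(
                1.0, np.max(np.abs(raw))
            ):
                converged = True
                break
            prev = raw.copy()
        warns = [] if converged or self.n_iter == 1 else [
            "w-NNLS did not converge; returning last iterate"
        ]
        resid_norm = np.linalg.norm(self.G - self.C @ raw, axis=0)
        diag = pd.DataFrame({"residual": resid_norm}, index=self.bulk.sample_ids)
        return _finalize(raw, self.type_names, self.method, diag, warns)


class NuSVRDeconvolution:
    """Linear nu-SVR of each z-scored sample on the signature columns.

    For each sample, identical (signature row, sample value) pairs are
    de-duplicated, genes are z-scored, and a linear nu-SVR is fitted for
    each nu in the grid; the nu minimizing root-mean-square fit error is
    kept. Negative coefficients are clipped to zero before simplex
    normalization.
    """

    method = "nusvr"

    def __init__(
        self,
        bulk: PseudoBulkDataset,
        signature: SignatureMatrix,
        nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75),
        svr_C: float = 1.0,
    ):
        self.bulk = bulk
        self.signature = signature
        self.nu_grid = tuple(nu_grid)
        self.svr_C = svr_C
        sig_rows, bulk_rows = _shared_rows(bulk, signature.gene_ids)
        if sig_rows.size < signature.n_types:
            raise ValueError("fewer shared genes than cell types")
        self.C = signature.values[sig_rows]
        self.G = bulk.expression[bulk_rows]

    def _fit_sample(self, g: np.ndarray) -> tuple[np.ndarray, float, float]:
        aug = np.column_stack([self.C, g])
        aug = np.unique(aug, axis=0)  # de-duplicate identical gene rows
        X, y = aug[:, :-1], aug[:, -1]
        y_sd = y.std()
        if y_sd == 0:
            raise ValueError("degenerate sample: constant expression")
        y_z = (y - y.mean()) / y_sd
        X_sd = X.std()
        X_z = (X - X.mean()) / (X_sd if X_sd > 0 else 1.0)
        best = None
        for nu in self.nu_grid:
            model = NuSVR(kernel="linear", nu=nu, C=self.svr_C)
            model.fit(X_z, y_z)
            rmse = float(np.sqrt(np.mean((model.predict(X_z) - y_z) ** 2)))
            if best is None or rmse < best[0]:
                best = (rmse, nu, model.coef_.ravel().copy())
        rmse, nu, coef = best
        return coef, nu, rmse

    def fit(self) -> DeconvolutionResult:
        K, n = self.signature.n_types, self.bulk.n_samples
        raw = np.zeros((K, n))
        nus = np.zeros(n)
        resid = np.zeros(n)
        warns: list[str] = []
        for j in range(n):
            coef, nu, rmse = self._fit_sample(self.G[:, j])
            coef = np.clip(coef, 0, None)
            if not np.any(coef > 0):
                warns.append(f"sample {self.bulk.sample_ids[j]}: all coefficients clipped")
                coef = np.full(K, 1.0 / K)  # flagged fallback keeps shapes valid
            raw[:, j] = coef
            nus[j] = nu
            resid[j] = rmse
        diag = pd.DataFrame(
            {"residual": resid, "nu": nus}, index=self.bulk.sample_ids
        )
        return _finalize(raw, self.signature.type_names, self.method, diag, warns)


def nnls_deconv(G: PseudoBulkDataset, C: SignatureMatrix) -> DeconvolutionResult:
    return NNLSDeconvolution(G, C).fit()


def wnnls_deconv(
    G: PseudoBulkDataset, reference: SingleCellDataset, n_iter: int = 5
) -> DeconvolutionResult:
    return WeightedNNLSDeconvolution(G, reference, n_iter=n_iter).fit()


def nusvr_deconv(
    G: PseudoBulkDataset,
    C: SignatureMatrix,
    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75),
) -> DeconvolutionResult:
    return NuSVRDeconvolution(G, C, nu_grid=nu_grid).fit()
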