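"""Reference-free deconvolution: simplex geometry and regularized NMF.

Both solvers estimate the composition matrix P from the bulk matrix alone.
The key geometric fact they exploit: after normalizing each gene's
expression across samples to sum 1, every gene row is a convex combination
of the K normalized proportion rows, and a gene expressed in exactly one
cell type (a marker) sits at a corner of that (K-1)-simplex.

* :class:`SimplexDeconvolution` denoises the gene cloud with a rank-K SVD
  projection, locates K corner genes by successive projection (greedy
  maximum-residual-norm with orthogonal deflation), and recovers per-sample
  proportions by non-negative regression of the corner rows onto the
  all-ones sample vector.
* :class:`MarkerNMF` minimizes ``||G - CP||_F^2 + lambda1*F1(C) +
  lambda2*F2(C)`` over C, P >= 0 with multiplicative updates, where F1
  penalizes off-dominant loadings of candidate marker genes (row-wise
  squared l2 on non-dominant entries) and F2 = trace(C' L C) with L the
  Laplacian of the gene-gene correlation graph.

Estimated components are anonymous; :func:`match_components` aligns them to
a ground-truth ordering by Hungarian assignment on per-component Pearson
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls as _nnls

from ._rng import child_rng
from .datasets import ProportionMatrix, PseudoBulkDataset
from .results import DeconvolutionResult

__all__ = [
    "UnlabeledProportions",
    "NMFConfig",
    "collinearity_filter",
    "estimate_k",
    "SimplexDeconvolution",
    "MarkerNMF",
    "simplex_deconv",
    "nmf_marker_deconv",
    "match_components",
]


@dataclass
class UnlabeledProportions:
    """K x n column-stochastic estimate with anonymous component indices."""

    values: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("values must be K x n with K >= 2")
        if not np.allclose(self.values.sum(axis=0), 1.0, atol=1e-8):
            raise ValueError("columns must sum to 1")

    @property
    def n_components(self) -> int:
        return self.values.shape[0]


@dataclass
class NMFConfig:
    """Settings for :class:`MarkerNMF`."""

    K: int
    lambda1: float = 0.0
    lambda2: float = 0.0
    n_iter: int = 500
    tol: float = 1e-7
    seed: int = 0
    marker_candidates: np.ndarray | None = None  # row indices into G
    graph_corr_threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


def _row_correlations(X: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation with constant rows mapped to 0."""
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc**2).sum(axis=1))
    safe = np.where(sd > 0, sd, 1.0)
    Z = Xc / safe[:, None]
    corr = Z @ Z.T
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    return corr


def collinearity_filter(
    G: PseudoBulkDataset,
    top_frac: float = 0.5,
    n_perm: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Keep mutually linear genes; returns row indices into ``G``.

    Each gene is scored by its maximum Pearson correlation with any other
    gene across samples. A null score distribution is built by permuting
    every gene's sample order independently ``n_perm`` times; genes whose
    score exceeds the null 95th percentile are kept, capped at ``top_frac``
    of the genes. ``n_perm=0`` keeps the top ``top_frac`` by score.
    """
    if G.n_samples < 3:
        raise ValueError("need at least 3 samples for the correlation null")
    X = np.asarray(G.expression, dtype=float)
    M = X.shape[0]
    corr = _row_correlations(X)
    np.fill_diagonal(corr, -np.inf)
    scores = corr.max(axis=1)

    cap = max(1, int(np.floor(top_frac * M)))
    if n_perm > 0:
        rng = child_rng(seed, "collinearity-null")
        null_scores = []
        for _ in range(n_perm):
            Xp = np.array([rng.permutation(row) for row in X])
            cp = _row_correlations(Xp)
            np.fill_diagonal(cp, -np.inf)
            null_scores.append(cp.max(axis=1))
        thresh = np.quantile(np.concatenate(null_scores), 0.95)
        keep = np.flatnonzero(scores > thresh)
    else:
        keep = np.arange(M)
    if keep.size > cap:
        order = keep[np.argsort(-scores[keep], kind="stable")]
        keep = np.sort(order[:cap])
    return keep


def estimate_k(G: PseudoBulkDataset, var_threshold: float = 0.99) -> int:
    """Smallest K whose top-K singular values explain >= var_threshold."""
    if not 0 < var_threshold <= 1:
        raise ValueError("var_threshold must lie in (0, 1]")
    X = np.asarray(G.expression, dtype=float)
    totals = X.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("degenerate zero-total column")
    s = np.linalg.svd(X / totals[None, :], compute_uv=False)
    frac = np.cumsum(s**2) / np.sum(s**2)
    return int(np.searchsorted(frac, var_threshold - 1e-12) + 1)


class SimplexDeconvolution:
    """Simplex-corner unmixing of a bulk matrix with K components."""

    method = "simplex"

    def __init__(self, bulk: PseudoBulkDataset, K: int, seed: int = 0):
        if K < 2:
            raise ValueError("K must be >= 2")
        if bulk.n_samples < K:
            raise ValueError("need at least K samples")
        self.bulk = bulk
        self.K = int(K)
        self.seed = seed
        self.corner_genes_: np.ndarray | None = None

    def fit(self) -> UnlabeledProportions:
        X = np.asarray(self.bulk.expression, dtype=float)
        row_sums = X.sum(axis=1)
        keep = np.flatnonzero(row_sums > 0)
        Xn = X[keep] / row_sums[keep][:, None]  # gene rows on the simplex

        # rank-K SVD denoising, then successive projection for corners
        U, s, Vt = np.linalg.svd(Xn, full_matrices=False)
        Z = U[:, : self.K] * s[: self.K]
        resid = Z.copy()
        corners: list[int] = []
        for _ in range(self.K):
            norms = np.linalg.norm(resid, axis=1)
            norms[corners] = -np.inf
            c = int(np.argmax(norms))
            corners.append(c)
            u = resid[c]
            nu = np.linalg.norm(u)
            if nu <= 1e-12:
                raise ValueError("degenerate geometry: collapsed corner")
            u = u / nu
            resid = resid - np.outer(resid @ u, u)

        R = Xn[corners]  # K x n, rows approx normalized proportion rows
        if np.linalg.matrix_rank(R) < self.K:
            raise ValueError("degenerate geometry: corner matrix rank < K")
        # choose per-row scales s >= 0 so that columns of diag(s) @ R sum to 1
        scale, _ = _nnls(R.T, np.ones(self.bulk.n_samples))
        P = np.clip(scale[:, None] * R, 0, None)
        sums = P.sum(axis=0)
        if np.any(sums <= 0):
            raise ValueError("degenerate geometry: empty sample composition")
        self.corner_genes_ = keep[np.array(corners)]
        return UnlabeledProportions(P / sums[None, :], method=self.method)


def _nndsvd_init(X: np.ndarray, K: int, rng: np.random.Generator):
    """Non-negative double SVD initialization (zeros filled with small mean)."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    W = np.zeros((X.shape[0], K))
    H = np.zeros((K, X.shape[1]))
    W[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(s[0]) * np.abs(Vt[0])
    for k in range(1, min(K, s.size)):
        u, v = U[:, k], Vt[k]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sigma = n_up * n_vp
            uu, vv = up / max(n_up, 1e-12), vp / max(n_vp, 1e-12)
        else:
            sigma = n_un * n_vn
            uu, vv = un / max(n_un, 1e-12), vn / max(n_vn, 1e-12)
        W[:, k] = np.sqrt(s[k] * sigma) * uu
        H[k] = np.sqrt(s[k] * sigma) * vv
    floor = X.mean() / 100.0
    W[W < floor] = floor * (1 + 0.01 * rng.random(np.count_nonzero(W < floor)))
    H[H < floor] = floor * (1 + 0.01 * rng.random(np.count_nonzero(H < floor)))
    return W, H


class MarkerNMF:
    """Marker- and graph-regularized NMF solved by multiplicative updates.

    The objective is ``||G - CP||_F^2 + lambda1 * F1(C) + lambda2 *
    trace(C' L C)`` with F1 the squared l2 norm of non-dominant entries of
    candidate marker rows (the dominant entry per row is its current
    argmax) and L the Laplacian of the gene correlation graph (edges where
    the Pearson correlation across samples exceeds the threshold).
    """

    method = "marker_nmf"

    def __init__(self, bulk: PseudoBulkDataset, config: NMFConfig):
        if np.any(bulk.expression < 0):
            raise ValueError("NMF requires a non-negative matrix")
        self.bulk = bulk
        self.cfg = config
        self.objective_path_: list[float] = []
        self.converged_: bool = False
        self.C_: np.ndarray | None = None

    # -- objective pieces -------------------------------------------------

    def _marker_mask(self, C: np.ndarray) -> np.ndarray:
        mask = np.zeros_like(C)
        rows = self.cfg.marker_candidates
        if self.cfg.lambda1 > 0 and rows is not None and len(rows):
            sub = C[rows]
            mask[rows] = 1.0
            mask[rows, np.argmax(sub, axis=1)] = 0.0
        return mask

    def _objective(self, X, C, P, W, D) -> float:
        val = float(np.linalg.norm(X - C @ P) ** 2)
        if self.cfg.lambda1 > 0:
            val += self.cfg.lambda1 * float(np.sum((self._marker_mask(C) * C) ** 2))
        if self.cfg.lambda2 > 0:
            val += self.cfg.lambda2 * float(
                np.sum((D[:, None] * C) * C) - np.sum(C * (W @ C))
            )
        return val

    def fit(self) -> tuple[np.ndarray, UnlabeledProportions]:
        cfg = self.cfg
        X = np.asarray(self.bulk.expression, dtype=float)
        eps = 1e-12
        rng = child_rng(cfg.seed, "nmf-init")
        C, P = _nndsvd_init(X, cfg.K, rng)

        if cfg.lambda2 > 0:
            corr = _row_correlations(X)
            np.fill_diagonal(corr, 0.0)
            W = (corr > cfg.graph_corr_threshold).astype(float)
            D = W.sum(axis=1)
        else:
            W = np.zeros((X.shape[0], X.shape[0]))
            D = np.zeros(X.shape[0])

        prev_obj = self._objective(X, C, P, W, D)
        self.objective_path_ = [prev_obj]
        for _ in range(cfg.n_iter):
            P *= (C.T @ X) / (C.T @ C @ P + eps)
            num = X @ P.T
            den = C @ (P @ P.T)
            if cfg.lambda1 > 0:
                den = den + cfg.lambda1 * (self._marker_mask(C) * C)
            if cfg.lambda2 > 0:
                num = num + cfg.lambda2 * (W @ C)
                den = den + cfg.lambda2 * (D[:, None] * C)
            C *= num / (den + eps)
            obj = self._objective(X, C, P, W, D)
            if obj > prev_obj * (1 + 1e-8) + 1e-8:
                raise RuntimeError("NMF objective increased beyond tolerance")
            self.objective_path_.append(obj)
            if prev_obj > 0 and (prev_obj - obj) / prev_obj < cfg.tol:
                self.converged_ = True
                break
            prev_obj = obj

        self.C_ = C
        sums = P.sum(axis=0)
        if np.any(sums <= 0):
            raise ValueError("degenerate factorization: empty composition column")
        return C, UnlabeledProportions(P / sums[None, :], method=self.method)


def simplex_deconv(G: PseudoBulkDataset, K: int, seed: int = 0) -> UnlabeledProportions:
    return SimplexDeconvolution(G, K, seed=seed).fit()


def nmf_marker_deconv(
    G: PseudoBulkDataset, cfg: NMFConfig
) -> tuple[np.ndarray, UnlabeledProportions]:
    return MarkerNMF(G, cfg).fit()


def match_components(
    est: UnlabeledProportions, truth: ProportionMatrix
) -> DeconvolutionResult:
    """Align anonymous components to the truth ordering.

    Hungarian assignment maximizing the sum of per-component Pearson
    correlations between estimated and true proportion rows; the estimate's
    rows are permuted into the truth's order.
    """
    if est.n_components != truth.n_types:
        raise ValueError("component count mismatch")
    K = truth.n_types
    sim = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            a, b = est.values[i], truth.values[j]
            if a.std() == 0 or b.std() == 0:
                sim[i, j] = 0.0
            else:
                sim[i, j] = float(np.corrcoef(a, b)[0, 1])
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows
    matched = est.values[perm]
    diag = pd.DataFrame(
        {"matched_component": perm, "match_correlation": sim[perm, np.arange(K)]},
        index=list(truth.type_names),
    )
    return DeconvolutionResult(
        proportions=ProportionMatrix(matched, list(truth.type_names)),
        method=est.method or "unlabeled",
        diagnostics=diag,
    )
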