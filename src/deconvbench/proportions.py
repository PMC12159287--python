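"""Dirichlet model for ground-truth cell-type compositions.

Proportions of K cell types across n bulk samples are drawn i.i.d. from a
Dirichlet distribution with concentration vector p = (p_1, ..., p_K). The
expected composition is gamma_k = p_k / p0 with p0 = sum_k p_k, and the
marginal variance of each component is gamma_k (1 - gamma_k) / (p0 + 1), so
p0 is the composition-variance dial: dividing p by 10 or 100 keeps the mean
composition fixed while increasing the spread, which is exactly how the
small / medium / large variation tiers are built.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import child_rng
from .datasets import ProportionMatrix

__all__ = [
    "DirichletSpec",
    "expected_proportions",
    "proportion_variance",
    "sample_proportions",
    "TISSUE_CONCENTRATIONS",
    "VARIATION_TIERS",
    "tier_concentration",
]

# Base concentration vectors per tissue preset (small-variation tier);
# medium and large tiers divide these by 10 and 100.
TISSUE_CONCENTRATIONS: dict[str, np.ndarray] = {
    "liver_lung_brain": np.array([3.3, 3.4, 3.3]),
    "blood": np.array([1.0, 2.5, 0.5, 0.8, 0.5, 0.5]),
    "pancreas": np.array([5.4, 3.5, 1.1, 0.5]),
    "brain": np.array([6.2, 2.0, 1.6, 13.1, 3.8]),
}

VARIATION_TIERS: dict[str, float] = {"small": 1.0, "medium": 10.0, "large": 100.0}


def tier_concentration(tissue: str, tier: str) -> np.ndarray:
    """Concentration vector for a tissue preset at a variation tier."""
    if tissue not in TISSUE_CONCENTRATIONS:
        raise KeyError(f"unknown tissue preset {tissue!r}")
    if tier not in VARIATION_TIERS:
        raise KeyError(f"unknown variation tier {tier!r}")
    return TISSUE_CONCENTRATIONS[tissue] / VARIATION_TIERS[tier]


def _check_positive(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("concentration vector must be 1-D and non-empty")
    if np.any(p <= 0):
        raise ValueError("all concentration parameters must be positive")
    return p


@dataclass
class DirichletSpec:
    """Dirichlet concentration vector plus sampling bookkeeping."""

    p: np.ndarray
    n_samples: int
    seed: int = 0
    type_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.p = _check_positive(self.p)
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.type_names is None:
            self.type_names = [f"type{k}" for k in range(self.p.size)]
        if len(self.type_names) != self.p.size:
            raise ValueError("type_names length mismatch")


def expected_proportions(p: np.ndarray) -> np.ndarray:
    """Expected composition gamma_k = p_k / sum(p)."""
    p = _check_positive(p)
    return p / p.sum()


def proportion_variance(p: np.ndarray) -> np.ndarray:
    """Marginal Dirichlet variances gamma_k (1 - gamma_k) / (p0 + 1)."""
    p = _check_positive(p)
    p0 = p.sum()
    gamma = p / p0
    return gamma * (1.0 - gamma) / (p0 + 1.0)


def sample_proportions(spec: DirichletSpec) -> ProportionMatrix:
    """Draw ``n_samples`` i.i.d. Dirichlet(p) compositions as columns.

    Uses numpy's Dirichlet sampler (normalized Gamma draws); deterministic
    per seed.
    """
    rng = child_rng(spec.seed, "dirichlet")
    draws = rng.dirichlet(spec.p, size=spec.n_samples).T  # K x n
    # guard against exact-zero components from extreme concentrations
    draws = np.clip(draws, 1e-12, None)
    draws /= draws.sum(axis=0, keepdims=True)
    return ProportionMatrix(values=draws, type_names=list(spec.type_names))
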