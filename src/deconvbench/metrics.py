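"""Scoring of estimated against true cell-type compositions.

Three metrics compare a truth matrix P and an estimate P-hat (both K x n,
column-stochastic):

* Pearson's correlation R = Cor(p, p-hat), pooled over all entries by
  default (per-sample mean available as a sensitivity mode);
* RMSD per sample: sqrt(sum_k (p_k - phat_k)^2 / K), averaged over samples;
* MAD per sample: (1/K) sum_k |p_k - phat_k|, averaged over samples.

MAD <= RMSD per sample by the power-mean inequality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import ProportionMatrix

__all__ = ["pearson_r", "rmsd", "mad", "evaluate", "MetricReport"]


def _pair(truth, est) -> tuple[np.ndarray, np.ndarray]:
    t = truth.values if isinstance(truth, ProportionMatrix) else np.asarray(truth, float)
    e = est.values if isinstance(est, ProportionMatrix) else np.asarray(est, float)
    if t.ndim == 1:
        t = t[:, None]
    if e.ndim == 1:
        e = e[:, None]
    if t.shape != e.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {e.shape}")
    return t, e


def pearson_r(truth, est, mode: str = "pooled") -> float:
    """Pearson correlation between true and estimated proportions.

    ``pooled`` flattens both K x n matrices into one vector pair;
    ``per_sample`` averages the per-column correlations.
    """
    t, e = _pair(truth, est)
    if mode == "pooled":
        tf, ef = t.ravel(), e.ravel()
        if tf.std() == 0 or ef.std() == 0:
            raise ValueError("zero variance in pooled vector")
        return float(np.corrcoef(tf, ef)[0, 1])
    if mode == "per_sample":
        rs = []
        for j in range(t.shape[1]):
            if t[:, j].std() == 0 or e[:, j].std() == 0:
                raise ValueError(f"zero variance in sample {j}")
            rs.append(np.corrcoef(t[:, j], e[:, j])[0, 1])
        return float(np.mean(rs))
    raise ValueError("mode must be 'pooled' or 'per_sample'")


def rmsd(truth, est) -> float:
    """Root-mean-square deviation per sample, averaged over samples."""
    t, e = _pair(truth, est)
    per_sample = np.sqrt(np.mean((t - e) ** 2, axis=0))
    return float(per_sample.mean())


def mad(truth, est) -> float:
    """Mean absolute deviation per sample, averaged over samples."""
    t, e = _pair(truth, est)
    return float(np.mean(np.abs(t - e), axis=0).mean())


def evaluate(
    truth,
    est,
    *,
    scenario: str = "",
    method: str = "",
    variation_tier: str = "",
    perturbation: str = "none",
    seed: int | None = None,
    mode: str = "pooled",
) -> dict:
    """One tidy metric row for a (scenario, method, tier, perturbation) cell."""
    t, _ = _pair(truth, est)
    return {
        "scenario": scenario,
        "method": method,
        "variation_tier": variation_tier,
        "perturbation": perturbation,
        "pearson_r": pearson_r(truth, est, mode=mode),
        "rmsd": rmsd(truth, est),
        "mad": mad(truth, est),
        "n_samples": t.shape[1],
        "seed": seed,
    }


class MetricReport:
    """Tidy table of metric rows; one row per (scenario, method, tier, perturbation)."""

    COLUMNS = [
        "scenario",
        "method",
        "variation_tier",
        "perturbation",
        "pearson_r",
        "rmsd",
        "mad",
        "n_samples",
        "seed",
    ]

    def __init__(self, rows: list[dict] | pd.DataFrame | None = None):
        if isinstance(rows, pd.DataFrame):
            df = rows
        else:
            df = pd.DataFrame(rows or [], columns=self.COLUMNS)
        self.table = df[self.COLUMNS].reset_index(drop=True)

    def append(self, row: dict) -> None:
        new = pd.DataFrame([row], columns=self.COLUMNS)
        self.table = (
            new if self.table.empty else pd.concat([self.table, new], ignore_index=True)
        )

    def concat(self, other: "MetricReport") -> "MetricReport":
        frames = [df for df in (self.table, other.table) if not df.empty]
        if not frames:
            return MetricReport()
        return MetricReport(pd.concat(frames, ignore_index=True))

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MetricReport":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def __len__(self) -> int:
        return len(self.table)
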