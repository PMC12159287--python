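"""Scenario orchestration: simulate -> perturb -> mix -> deconvolve -> score.

A :class:`ScenarioConfig` (loadable from YAML) declares one benchmark
scenario: the synthetic cell-level generator settings, a Dirichlet
composition preset (tissue + variation tiers, or a custom concentration
vector), optional perturbations of the bulk-generating copy, optional
reference discrepancies, the methods to run and a master seed.
:func:`run_scenario` executes the full flow and returns a
:class:`~deconvbench.metrics.MetricReport` with one row per
(tier, perturbation, method); :func:`run_benchmark_suite` concatenates the
reports of every config in a directory.

Reference-based methods receive the pristine reference copy (optionally
platform-shifted or variance-reduced to create a controlled discrepancy);
reference-free methods see only the bulk matrix. The bulk-generating copy
is the one that perturbations act on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._rng import child_seed
from .datasets import ProportionMatrix, PseudoBulkDataset, SingleCellDataset
from .metrics import MetricReport, evaluate
from .mixing import column_normalize, filter_genes, ideal_mix
from .perturb import PerturbationSpec, apply_perturbation
from .proportions import DirichletSpec, sample_proportions, tier_concentration
from .reference_based import (
    NNLSDeconvolution,
    NuSVRDeconvolution,
    WeightedNNLSDeconvolution,
    build_signature,
)
from .reference_free import (
    MarkerNMF,
    NMFConfig,
    SimplexDeconvolution,
    collinearity_filter,
    match_components,
)
from .singlecell import SingleCellSpec, generate_single_cell_dataset, platform_shift, reduce_variability

__all__ = ["ScenarioConfig", "run_scenario", "run_benchmark_suite"]

REFERENCE_BASED = ("nnls", "wnnls", "nusvr")
REFERENCE_FREE = ("simplex", "marker_nmf")


@dataclass
class ScenarioConfig:
    """Declarative description of one robustness/resilience scenario."""

    name: str
    singlecell: dict
    dirichlet: dict  # {"tissue": ..., } or {"p": [...]}
    tiers: list[str] = field(default_factory=lambda: ["small", "medium", "large"])
    methods: list[str] = field(default_factory=lambda: list(REFERENCE_BASED + REFERENCE_FREE))
    cells_per_sample: int = 500
    n_samples: int = 50
    perturbations: list[dict] = field(default_factory=list)
    discrepancy: dict = field(default_factory=dict)
    n_markers_per_type: int = 50
    use_intended_truth: bool = False
    metric_mode: str = "pooled"
    nmf: dict = field(default_factory=dict)
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("methods list must be non-empty")
        unknown = set(self.methods) - set(REFERENCE_BASED + REFERENCE_FREE)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if "p" not in self.dirichlet and "tissue" not in self.dirichlet:
            raise ValueError("dirichlet must give 'p' or a 'tissue' preset")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "outdir"},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def concentration(self, tier: str) -> np.ndarray:
        if "p" in self.dirichlet:
            base = np.asarray(self.dirichlet["p"], dtype=float)
            from .proportions import VARIATION_TIERS

            return base / VARIATION_TIERS[tier]
        return tier_concentration(self.dirichlet["tissue"], tier)


def _prepare_copies(cfg: ScenarioConfig):
    """Generate the cell pool and derive the bulk-generating and reference copies."""
    sc_spec = SingleCellSpec(**{**cfg.singlecell, "seed": child_seed(cfg.seed, "cells")})
    base = generate_single_cell_dataset(sc_spec)
    bulk_copy = base
    reference_copy = base

    disc = cfg.discrepancy or {}
    if disc.get("reduce_variability"):
        bulk_copy = reduce_variability(
            bulk_copy, float(disc["reduce_variability"]), seed=child_seed(cfg.seed, "shrink")
        )
    ps = disc.get("platform_shift")
    if ps:
        target = ps.get("target", "reference")
        shifted = lambda d: platform_shift(  # noqa: E731
            d,
            bias_sigma=float(ps.get("bias_sigma", 0.0)),
            dropout_delta=float(ps.get("dropout_delta", 0.0)),
            seed=child_seed(cfg.seed, "platform"),
        )
        if target == "reference":
            reference_copy = shifted(reference_copy)
        elif target == "bulk":
            bulk_copy = shifted(bulk_copy)
        else:
            raise ValueError("platform_shift target must be 'reference' or 'bulk'")
    return bulk_copy, reference_copy


def _run_methods(
    cfg: ScenarioConfig,
    bulk: PseudoBulkDataset,
    reference: SingleCellDataset | None,
    tier: str,
    perturbation: str,
    report: MetricReport,
) -> None:
    truth = bulk.intended if cfg.use_intended_truth else bulk.truth
    K = truth.n_types
    signature = None
    needs_reference = [m for m in cfg.methods if m in REFERENCE_BASED]
    if needs_reference:
        assert reference is not None
        signature = build_signature(reference, cfg.n_markers_per_type)

    for method in cfg.methods:
        if method == "nnls":
            res = NNLSDeconvolution(bulk, signature).fit()
            est = res.proportions.reorder(truth.type_names)
        elif method == "wnnls":
            res = WeightedNNLSDeconvolution(bulk, reference).fit()
            est = res.proportions.reorder(truth.type_names)
        elif method == "nusvr":
            res = NuSVRDeconvolution(bulk, signature).fit()
            est = res.proportions.reorder(truth.type_names)
        elif method == "simplex":
            unlabeled = SimplexDeconvolution(
                bulk, K, seed=child_seed(cfg.seed, "simplex", tier)
            ).fit()
            est = match_components(unlabeled, truth).proportions
        elif method == "marker_nmf":
            nmf_kwargs = dict(
                K=K,
                lambda1=0.1,
                lambda2=0.1,
                n_iter=400,
                seed=child_seed(cfg.seed, "nmf", tier),
            )
            nmf_kwargs.update(cfg.nmf)
            nmf_cfg = NMFConfig(**nmf_kwargs)
            if nmf_cfg.lambda1 > 0 and nmf_cfg.marker_candidates is None:
                nmf_cfg.marker_candidates = collinearity_filter(
                    bulk, top_frac=0.2, n_perm=0
                )
            _, unlabeled = MarkerNMF(bulk, nmf_cfg).fit()
            est = match_components(unlabeled, truth).proportions
        else:  # pragma: no cover - guarded in __post_init__
            raise ValueError(method)
        report.append(
            evaluate(
                truth,
                est,
                scenario=cfg.name,
                method=method,
                variation_tier=tier,
                perturbation=perturbation,
                seed=cfg.seed,
                mode=cfg.metric_mode,
            )
        )


def run_scenario(cfg: ScenarioConfig) -> MetricReport:
    """Execute one scenario end to end; deterministic for a fixed config."""
    bulk_copy, reference_copy = _prepare_copies(cfg)
    perturb_specs = [("none", None)] + [
        (_perturb_label(p), PerturbationSpec(**p)) for p in cfg.perturbations
    ]
    needs_reference = any(m in REFERENCE_BASED for m in cfg.methods)

    report = MetricReport()
    for tier in cfg.tiers:
        p_vec = cfg.concentration(tier)
        if p_vec.size != len(bulk_copy.type_names):
            raise ValueError(
                f"concentration length {p_vec.size} != K={len(bulk_copy.type_names)}"
            )
        props = sample_proportions(
            DirichletSpec(
                p=p_vec,
                n_samples=cfg.n_samples,
                seed=child_seed(cfg.seed, "dirichlet", tier),
                type_names=list(bulk_copy.type_names),
            )
        )
        for label, pspec in perturb_specs:
            source = bulk_copy if pspec is None else apply_perturbation(bulk_copy, pspec)
            bulk = ideal_mix(
                source,
                props,
                cells_per_sample=cfg.cells_per_sample,
                seed=child_seed(cfg.seed, "mix", tier, label),
            )
            bulk = column_normalize(filter_genes(bulk))
            _run_methods(
                cfg,
                bulk,
                reference_copy if needs_reference else None,
                tier,
                label,
                report,
            )

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"config_hash={cfg.config_hash()} seed={cfg.seed}"
        report.to_tsv(out / f"{cfg.name}.metrics.tsv", header_comment=header)
    return report


def _perturb_label(p: dict) -> str:
    kind = p["kind"]
    if kind == "mean_shift":
        return f"mean_shift:{p.get('fraction', 0)}"
    if kind == "truncate":
        return f"truncate:{p.get('side', 'top')}:{p.get('q', 0.1)}"
    return f"factor:{p.get('factor', 1.0)}"


def run_benchmark_suite(config_dir: str | Path) -> MetricReport:
    """Run every YAML config in a directory and concatenate the reports."""
    paths = sorted(Path(config_dir).glob("*.yaml")) + sorted(
        Path(config_dir).glob("*.yml")
    )
    if not paths:
        raise ValueError(f"no configs found under {config_dir}")
    configs = [ScenarioConfig.from_yaml(p) for p in paths]
    names = [c.name for c in configs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate scenario ids in suite")
    combined = MetricReport()
    for cfg in configs:
        combined = combined.concat(run_scenario(cfg))
    return combined
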