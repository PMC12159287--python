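# deconvbench

Robustness and resilience benchmarking of bulk RNA-seq cell-type
deconvolution methods on simulated pseudo-bulk tissues.

## The problem

Bulk tissue RNA-seq measures a mixture: each sample's expression profile is
a weighted sum of the profiles of the cell types composing it. Computational
deconvolution estimates those weights. Under the standard linear mixing
model

```
G = C P + ε,        E(ε) = 0
```

`G` (genes × samples) is the bulk expression matrix, `C` (genes × K) holds
the expected expression of each of the K cell types, `P` (K × samples) is
the column-stochastic matrix of cell-type proportions, and ε is mixing
noise. **Reference-based** methods take `C` as known — built from a
single-cell or sorted-cell reference — and estimate only `P`;
**reference-free** methods estimate both factors from `G` alone.

Two questions decide which family to trust in practice:

* **Robustness** — how stable is accuracy across tissue types and across
  the amount of variation in cell composition, when the reference faithfully
  describes the cells in the mixture?
* **Resilience** — how much accuracy survives when the reference and the
  cells actually composing the bulk disagree (platform shifts, distorted
  means, truncated cell populations, over-smoothed synthetic references)?

`deconvbench` answers both with fully simulated, fully controlled inputs:
no downloads, every experiment reproducible from one integer seed.

## What is in the box

| stage | module | contents |
|---|---|---|
| cell-level simulation | `singlecell` | negative-binomial counts, planted disjoint marker blocks, log-normal library sizes; discrepancy operators `reduce_variability` and `platform_shift` |
| composition model | `proportions` | Dirichlet(p) ground truth; γ = p/p₀ is the mean composition, p₀ = Σpₖ the variance dial; presets for four tissue configurations × three variation tiers (p, p/10, p/100) |
| pseudo-bulk construction | `mixing` | ideal mixing (multinomial cell sampling + summing), low-count gene filter, counts-per-million column normalization |
| perturbations | `perturb` | mean shifting (+10/30/50/70 % of the within-type mean), top/bottom 10 % cell truncation, global scaling (×0.4/0.8/1.2/1.8) |
| reference-based solvers | `reference_based` | t-statistic signature construction; NNLS; iteratively re-weighted NNLS (weights favour low within-type, high between-type variance); linear ν-SVR over a ν grid |
| reference-free solvers | `reference_free` | mutual-linearity gene filter with permutation null, SVD rank estimation, simplex-corner unmixing via successive projection, marker/graph-regularized NMF, Hungarian component matching |
| scoring | `metrics` | pooled Pearson R, per-sample RMSD and MAD, tidy `MetricReport` |
| orchestration | `pipeline` / `cli` | YAML scenario configs, `run_scenario` / `run_benchmark_suite`, `deconvbench` CLI |

Solvers follow a model/results pattern: construct a model from a
pseudo-bulk dataset plus a signature or reference, call `.fit()`, get a
`DeconvolutionResult` with the estimate, per-sample diagnostics and a
`summary()` table.

## Worked example

```python
import deconvbench as db

cfg = db.ScenarioConfig(
    name="pancreas_demo",
    singlecell=dict(n_genes=600, n_cells_per_type=60, n_types=4),
    dirichlet=dict(tissue="pancreas"),
    tiers=["small", "medium"],
    methods=["nnls", "wnnls", "nusvr", "simplex", "marker_nmf"],
    n_samples=50,
    seed=42,
)
report = db.run_scenario(cfg)
print(report.table[["method", "variation_tier", "pearson_r", "rmsd", "mad"]]
      .round(4).to_string(index=False))
```

```
    method variation_tier  pearson_r   rmsd    mad
      nnls          small     0.9993 0.0075 0.0063
     wnnls          small     0.9993 0.0073 0.0062
     nusvr          small     0.9993 0.0074 0.0062
   simplex          small     0.9940 0.0917 0.0806
marker_nmf          small     0.6127 0.1823 0.1458
      nnls         medium     0.9998 0.0053 0.0041
     wnnls         medium     0.9998 0.0052 0.0040
     nusvr         medium     0.9998 0.0060 0.0047
   simplex         medium     0.9947 0.1289 0.1130
marker_nmf         medium     0.9796 0.1024 0.0891
```

Reading the table: the three reference-based solvers sit at R ≈ 0.999 in
both tiers — with a faithful reference, composition variance barely matters.
The reference-free solvers depend on it: marker-regularized NMF jumps from
R = 0.61 at the small-variation tier (p₀ ≈ 10.5) to R = 0.98 at the medium
tier (p₀ ≈ 1.05), because wider composition swings make marker genes'
expression trace the proportions more identifiably. RMSD/MAD are absolute
per-sample deviations on the proportion scale (0.0075 ≈ three-quarters of a
percentage point of composition).

The same flow runs from the shell:

```bash
deconvbench simulate-cells --n-genes 600 --n-cells-per-type 60 --n-types 4 \
    --seed 1 -o cells.tsv
deconvbench simulate-proportions --tissue pancreas --tier medium \
    --n-samples 50 --seed 2 -o props.tsv
deconvbench mix cells.tsv props.tsv --seed 3 -o bulk.tsv
deconvbench deconv bulk.tsv --method wnnls --reference cells.tsv -o est.tsv
deconvbench evaluate bulk.tsv.truth est.tsv
```

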