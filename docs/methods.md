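# Methods

This note documents the models, the numerical choices, and what the
simulations do and do not show. Everything stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is quoted from external
runs.

## Mixing model and ground truth

All simulations instantiate the linear model `G = C P + ε`, `E(ε) = 0`,
with `G` genes × samples, `C` genes × K, `P` K × samples column-stochastic.
Pseudo-bulk samples are built by *ideal mixing*: for sample j, cell-type
counts are drawn from a multinomial over `cells_per_sample` cells with
probabilities `P[:, j]`; that many cells are sampled with replacement from
each type's pool and their integer count vectors summed. The realized
multinomial fractions — not the Dirichlet draw — are the default ground
truth, because under ideal mixing they are the exact composition of the
constructed sample; the intended draw is kept alongside and can be selected
via `use_intended_truth`. Conservation is exact: a pseudo-bulk column total
equals the summed totals of its constituent cells in integer arithmetic.

`cells_per_sample` defaults to 500: large enough that realized fractions
track the Dirichlet draw (multinomial SE ≈ √(γ(1−γ)/500) ≈ 0.02), small
enough to keep full scenarios fast. Scenarios default to 50 samples.

## Composition model

Proportions are i.i.d. Dirichlet(p). With p₀ = Σpₖ and γ = p/p₀, the
marginal variance of component k is γₖ(1−γₖ)/(p₀+1): γ fixes the mean
composition and p₀ alone dials the variance. Shipped tissue presets
(concentration vectors for a 3-type liver/lung/brain mixture, 6-type blood,
4-type pancreatic islet, 5-type brain configuration) each come in three
variation tiers — the base vector, /10, and /100 — so mean composition is
held fixed while compositional spread grows roughly tenfold per tier.
Sampling uses numpy's Dirichlet generator (normalized Gamma draws) and is
deterministic per seed. The liver/lung/brain preset keeps its slightly
asymmetric base vector (3.3, 3.4, 3.3) verbatim even though it is nearly
symmetric; γ₂ = 0.34 ≠ 1/3 exactly.

## Synthetic cell-level data

The generator emulates the statistical shape of real single-cell count
data without fitting any real dataset:

* per-gene baseline means log-normal around `base_mean` (5.0) with spread
  `gene_sigma` (0.6; 0 makes all baselines equal, which the mean-recovery
  tests use);
* K disjoint marker blocks, `marker_frac` (0.05) of genes each, elevated
  `marker_fold`-fold (5.0) in the owning type only — markers are therefore
  enriched, not pure, which is the realistic regime for the reference-free
  solvers' identifiability assumptions (set `marker_fold → 1` to switch the
  assumption off);
* negative-binomial counts with variance m + `dispersion`·m² (dispersion
  0.3; 0 gives Poisson), scaled by a per-cell log-normal library factor
  with sigma `libsize_sigma` (0.3, mean fixed at 1).

Defaults were chosen once as plausible for droplet-style single-cell counts
at desk scale and are not tuned per experiment.

What the generator does **not** emulate: gene–gene correlation beyond
co-membership in marker blocks, batch structure, subject-level variation,
zero-inflation beyond what the NB produces, or realistic gene-length /
GC effects. Passing benchmarks here therefore demonstrate correctness of
the machinery and the direction of the robustness/resilience effects, not
performance on any real tissue.

Two discrepancy operators create controlled reference/bulk mismatch:

* `reduce_variability(shrink)` pulls each cell toward its type mean
  (shrink = 1 collapses the type), emulating simulator-generated references
  that are much less variable than real data. It preserves per-type means
  up to rounding and uses banker's rounding (`np.rint`) when re-integerizing.
* `platform_shift(bias_sigma, dropout_delta)` applies one multiplicative
  log-normal factor per gene, shared across cells, plus extra per-gene
  dropout of nonzero entries — a stylized platform/assay effect (e.g.
  single-cell vs single-nucleus references). Zeros never become nonzero.

## Perturbations of the bulk-generating copy

Three manipulations act on the copy used to build pseudo-bulk while the
reference copy stays pristine: mean shifting (add a fraction of the
within-type gene mean; grid 0.1/0.3/0.5/0.7), truncation (drop the
floor(q·n) top- or bottom-total cells per type, q = 0.1), and factoring
(global multiplication; grid 0.4/0.8/1.2/1.8). Mean shifting and factoring
round half-up (floor(x + 0.5)) to stay count-valued; the rule is fixed so
the worked examples are reproducible to the integer. Factoring is provably
inert after column normalization up to rounding — the tests bound the
residual distortion by the propagated half-unit-per-cell rounding error.
"Most/least expressed cells" for truncation means ranking by per-cell total
counts. Factoring is applied globally (one factor for all types); a
per-type variant would change relative type abundances and is deliberately
out of scope.

## Bulk post-processing

Genes are removed when fewer than 10 counts occur in at least 80 % of
samples (strict/inclusive exactly as stated); the filter is idempotent.
Columns are then rescaled to a fixed total, 10⁶ by default (CPM).

## Reference-based solvers

The signature matrix is built from the reference by normalizing every cell
to equal totals (CPM), averaging within type, and selecting per type the
`n_markers_per_type` (default 50) genes with the largest Welch t-statistic
(type vs rest), ties broken by gene order; the signature rows are the
union of selections.

* **NNLS** solves min‖Cp − g‖₂, p ≥ 0 per sample (scipy's Lawson–Hanson),
  then normalizes p to the simplex.
* **Weighted NNLS** weights genes by
  w_g = between-type variance of the mean profiles /
  (pooled within-type variance + per-gene residual variance + 1e-8),
  re-estimating residual variance across samples after each of `n_iter`
  (5) passes. With equal variances everywhere the weights are constant and
  the estimate reduces to NNLS; with heteroscedastic noise matched by
  reference within-type variance it is strictly better (paired sign test in
  the suite). This is a single-level analogue of published weighted-least-
  squares deconvolution; tree-guided recursion and subject-level weighting
  are not implemented.
* **ν-SVR** fits a linear ν-support-vector regression of each sample on
  the signature columns for ν ∈ {0.25, 0.5, 0.75}, keeping the ν with the
  smallest fit RMSE. Before fitting, identical (signature row, sample
  value) pairs are de-duplicated and genes are z-scored, making the
  estimate invariant to duplicated rows and to rescaling of G. Negative
  coefficients are clipped to zero; a sample whose coefficients all clip is
  flagged and assigned the uniform composition rather than 0/0. Published
  batch correction and expression purification layers are out of scope.

All three are invariant to positive rescaling of G after simplex
normalization. Exact recovery on noiseless separable mixtures holds when
signature columns have equal totals (equal per-cell mRNA content); with
unequal totals, normalization-based pipelines recover proportions only up
to per-type scale — a known, real limitation shared by CPM-referenced
deconvolution generally.

## Reference-free solvers

Row-normalizing each gene's expression across samples places every gene in
the convex hull of the K normalized proportion rows; genes expressed in one
type sit at the corners.

* **Collinearity filter**: a gene's score is its maximum Pearson
  correlation with any other gene; the null distribution comes from
  permuting each gene's samples independently (`n_perm` times, default 10)
  and genes above the null 95th percentile are kept, capped at `top_frac`.
  `n_perm = 0` keeps the top fraction by score deterministically.
* **Rank estimation**: smallest K whose top singular values of the
  column-normalized matrix explain ≥ `var_threshold` of total variance. K
  is taken as known in scenarios (the benchmark evaluates estimation of P,
  not of K); `estimate_k` is available but optional.
* **Simplex-corner unmixing**: rank-K SVD projection of the gene cloud,
  then successive projection — greedily take the point of maximum residual
  norm and deflate its direction, K times. (The projection is to K
  dimensions in cone form rather than K−1 after centering: orthogonal
  deflation can extract only as many directions as the ambient rank, so the
  affine variant cannot reach all K corners.) Corner gene rows estimate the
  normalized proportion rows up to per-row scale; the scales are recovered
  by non-negative least squares against the all-ones vector (each sample's
  composition must sum to 1), and columns are finally simplex-normalized.
  Exact on noiseless separable data. SISAL-style robust simplex fitting is
  not implemented; successive projection is deterministic and adequate when
  near-pure marker genes exist, which the generator plants.
* **Marker/graph-regularized NMF** minimizes
  ‖G − CP‖²_F + λ₁F₁(C) + λ₂·tr(CᵀLC), C, P ≥ 0, by multiplicative
  updates. F₁ is the squared ℓ₂ norm of the non-dominant entries of
  candidate marker rows (dominant = row argmax, recomputed each iteration;
  switching the argmax can only decrease the penalty, so the objective
  stays monotone). F₂ uses the Laplacian of the gene graph with edges where
  the across-sample correlation exceeds 0.9; the Laplacian is split W/D
  between update numerator and denominator in the standard graph-NMF way,
  preserving monotonicity. λ₁ and λ₂ default to 0.1 in scenarios, with
  marker candidates taken from the collinearity filter. Both penalty forms
  are this package's instantiation of "solvability + manifold"
  regularization — the published penalties are only named, not specified,
  in the literature this emulates. Initialization is non-negative double
  SVD with zeros floored at mean(G)/100 (multiplicative updates cannot
  leave zero), with a seed-controlled jitter on the floor; the objective
  guard raises if an update ever increases the objective beyond 1e-8
  relative slack. Convergence: relative objective change < `tol` (1e-7) or
  `n_iter` (400–500) iterations.
* **Component matching**: anonymous components are aligned to the truth by
  Hungarian assignment maximizing summed per-component Pearson
  correlations. This is the package's explicit scoring choice for
  "fractions without annotation"; constant rows get correlation 0.

## Metrics

Pooled Pearson R flattens both K × n matrices into one vector pair — one R
per scenario, consistent with pooling all samples and types in a scatter
plot; a per-sample mode (mean of per-column correlations) is available for
sensitivity analysis. RMSD = √(Σₖ(pₖ−p̂ₖ)²/K) and MAD = (1/K)Σₖ|pₖ−p̂ₖ| are
computed per sample and averaged across samples by the arithmetic mean
(the aggregation choice is this package's; single per-scenario values do
not determine it). MAD ≤ RMSD ≤ 1 always for simplex columns.

## Seeds and determinism

One master seed per scenario; every stage derives an independent child
stream by hashing a short tag path into a `SeedSequence` spawn key, so a
single stage re-run in isolation sees exactly the stream it saw inside the
pipeline. All iterative solvers are deterministic given the config; the
same config produces byte-identical metric reports.

## Problem sizes

Scenario-level checks run at 600 genes, 4 types × 60 cells, 50 samples of
500 cells, 10 replicates — sizes chosen so that the Monte-Carlo standard
errors are well below the effect sizes being demonstrated while full
suites execute in seconds. The trend checks (reference-free accuracy rising
from the small to the medium variation tier; reference-based RMSD rising
monotonically along the platform-bias grid 0 → 0.25 → 0.5 → 1.0) are
asserted in ≥ 9 of 10 replicates rather than on means, which is the
stronger, distribution-free form of the claim.

## Known limitations

* Desk-scale analogues, not re-implementations: no batch correction,
  high-resolution purification, tree-guided recursion, SISAL, or the exact
  published NMF penalty forms.
* The generator's marker blocks are disjoint by construction; real marker
  programs overlap, so reference-free identifiability is easier here than
  in real tissue.
* Equal expected mRNA content per cell type is not enforced in the
  generator (marker elevation shifts type totals slightly), so even
  noiseless pipelines carry a small, realistic composition bias
  (R ≈ 0.999 rather than 1 for reference-based solvers).
* ε-regularization constants (1e-8 in w-NNLS weights, 1e-12 in NMF
  denominators) are fixed, not adaptive.
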