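# srtjoint

Joint imputation and deconvolution for paired spatially resolved
transcriptomics (SRT) slices.

Tissue atlases increasingly profile the same tissue with two SRT platforms
with complementary strengths: a high-resolution platform measuring a targeted
gene panel at (sub)cellular resolution (e.g. 10x Xenium, MERFISH), and a
lower-resolution platform measuring the whole transcriptome from
multicellular spots (e.g. 10x Visium, Slide-seq). `srtjoint` integrates one
slice of each kind through a shared factor model, simultaneously

- **imputing** off-panel gene expression at high spatial resolution, and
- **deconvolving** each low-resolution spot into latent cell-type mixtures.

It is written for computational biologists working with registered pairs of
SRT slices: the inputs are two count matrices with micrometer coordinates and
a (precomputed) spot-to-spot spatial mapping.

## Model

Let `A_X ∈ ℕ^{|S_X|×|G_X|}` be the high-resolution counts over panel `G_X`,
`A_V ∈ ℕ^{|S_V|×|G_V|}` the low-resolution counts with `G_X ⊂ G_V`, and
`Γ ∈ {0,1}^{|S_X|×|S_V|}` a binary mapping sending each high-resolution spot
to at most one low-resolution spot (built by nearest-spot matching within
100 µm on shared coordinates). Both observations are modeled as Poisson draws
from a latent high-resolution, whole-transcriptome mean with a rank-`h`
nonnegative factorization, written in count-scaled form `diag(N) P Q` where
`N > 0` are per-spot totals and `P` (spots × factors) and `Q`
(factors × genes) are row-stochastic. The objective is

```
min  PoiLoss(A_X ; diag(N) P Q_X) + PoiLoss(A_V ; Mᵀ P Q diag(φ))
     + ω(k) · (−Σ P log P)  +  l2 · Σ(raw²)
```

with `PoiLoss(Y;Z) = Σ(Z − Y log Z)`, `Q_X` the panel columns of `Q`, `M ≥ 0`
the per-spot count mass flowing into each mapped low-resolution spot
(`M ∘ (1−Γ) = 0`), and `φ > 0` an optional gene-wise platform-scaling factor
(fixed to 1 off the trained panel). The entropy term with schedule
`ω = exp(k/λ)` sharpens spot-to-factor assignments over training; the ridge
term stabilizes the unconstrained parameters. All constraints hold by
construction — `P`, `Q` are row-softmaxes and `N`, `M`, `φ` exponentials of
free parameters — and the model is trained with Adam (best of several random
restarts). Imputed expression for gene `g` is `diag(N) P Q_g`; low-resolution
mixtures are the row-normalized `Mᵀ P`; hard cell-type calls are
`argmax_j P[i,j]`.

## Worked example

Simulate a paired dataset (3 cell types on a checkerboard, 60 high-res spots
feeding 12 low-res spots, 30 genes with a 20-gene panel, double coverage),
then run the 4-fold holdout imputation protocol and deconvolve:

```python
import srtjoint as sj
from srtjoint.evaluation import holdout_evaluate_baseline

sim = sj.SimulationConfig(grid_side=4, n_types=3, coverage=2.0, n_genes=30,
                          panel_size=20, n_x_spots=60, n_v_spots=12, seed=0)
data, truth = sj.simulate_pair(sim)

cfg = sj.ModelConfig(h=3, lambda_entropy=1000.0, epochs=2000, restarts=3, seed=100)
scheme = sj.make_folds(data.panel, n_folds=4, seed=0)
result = sj.holdout_evaluate(data, cfg, scheme)
print(f"mean holdout R^2 (model):      {result.mean_r2:.3f}")

base = holdout_evaluate_baseline(data, scheme, "A")
print(f"mean holdout R^2 (baseline A): {base.mean_r2:.3f}")

model = sj.fit(data, sj.ModelConfig(h=3, lambda_entropy=500.0, epochs=2000,
                                    restarts=3, seed=100))
mixtures, empty = sj.deconvolve_visium(model)
cos = sj.cosine_similarity_matrix(sj.assign_cell_types(model), truth.cell_type)
_, mean_js = sj.score_deconvolution(mixtures, empty, truth.v_mixture,
                                    sj.match_factors(cos))
print(f"mean mixture JS divergence:    {mean_js:.4f}")
```

Output:

```
mean holdout R^2 (model):      0.807
mean holdout R^2 (baseline A): 0.333
mean mixture JS divergence:    0.0002
```

The first two lines are the holdout imputation score — for each fold of panel
genes the model is refit with those genes hidden from the high-resolution
slice, their expression is imputed, and each gene is scored by squared
Pearson correlation against the held-out counts. The model (0.807) clearly
beats the mapping-only baseline that copies the mapped low-resolution spot's
counts (0.333). The last line says the deconvolved per-spot cell-type
mixtures sit essentially on top of the ground truth (Jensen–Shannon
divergence near 0, out of a maximum of ln 2 ≈ 0.693).

The same pipeline is available from the shell via the `srtjoint` CLI
(`simulate`, `fit`, `impute`, `deconvolve`, `evaluate`, `baseline`
subcommands), each writing a manifest JSON with the effective configuration
and seeds.

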