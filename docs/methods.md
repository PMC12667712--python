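# Methods

## Data model

A slice is a pair `(A, S)`: a nonnegative integer count matrix over
spots × genes and per-spot 2-D coordinates in micrometers. A paired dataset
holds a high-resolution targeted-panel slice (`A_X`, panel `G_X`), a
low-resolution whole-transcriptome slice (`A_V`, genes `G_V ⊇ G_X`), and a
binary mapping `Γ` with at most one nonzero per row, assigning each
high-resolution spot to the low-resolution spot whose capture area it falls
in. `Γ` is built by nearest-spot matching on shared (pre-registered)
coordinates with a 100 µm cutoff by default; computing the registration
itself is out of scope — any external SRT alignment tool's output can be
used. Nearest-spot ties are broken toward the lowest low-resolution spot
index, making the mapping deterministic and order-stable. Gene matching is
case-sensitive exact string equality; no symbol aliasing is attempted.

By default the modeled gene universe is the high-resolution panel (shared
genes plus any holdout genes), with explicitly requested low-resolution
genes appended; modeling the full low-resolution transcriptome is available
via the `gene_universe="all"` config option. Out-of-panel genes carry no
high-resolution likelihood term and only inform `Q` through the aggregated
low-resolution counts.

## Model and inference

Both slices are Poisson observations of one latent high-resolution,
whole-transcriptome mean with a rank-`h` NMF in count-scaled form
`diag(N) P Q`: `N[i] > 0` is the inferred total count of spot `i`, `P[i]`
its factor mixture (row-stochastic), `Q[t]` the expression profile of factor
`t` (row-stochastic). The two forms are interchangeable: for any nonnegative
`W, H` (with no all-zero `H` row) there are `N, P, Q` with
`diag(N) P Q = W H` — move each factor's expression mass `Σ_g H[t,g]` into
the spot loadings, then split row totals from row compositions. The
implementation verifies this round trip to 1e-10. The aggregation weights
are reparameterized the same way, `M = diag(N) K`, so `M[i,j]` is the count
mass spot `i` contributes to low-resolution spot `j`.

The training objective is

```
PoiLoss(A_X ; diag(N) P Q_X) + PoiLoss(A_V ; Mᵀ P Q diag(φ))
  + ω(k)·(−Σ P log P)   [if λ is set]
  + l2 · Σ(raw parameters²)
```

Constraints hold by construction rather than by penalty: `P` and `Q` are
row-softmaxes of unconstrained logit matrices; `N`, `M`, `φ` are
exponentials of log-parameters; `M`'s log-parameters exist only on the
support of `Γ`, so `M ∘ (1−Γ) = 0` exactly; `φ` is parameterized only over
trained panel genes and is exactly 1 elsewhere (reducing nonidentifiability,
since off-panel genes have no high-resolution anchor). Spots with empty `Γ`
rows simply contribute nothing to the low-resolution term.

Training is Adam (moment decays 0.9/0.999, eps 1e-8) implemented directly
over the raw parameter arrays, with hand-derived analytic gradients; a
finite-difference check in the test suite bounds the relative gradient error
at ~1e-7. The entropy term uses the natural log and its weight
`ω = exp(k/λ)` is evaluated per epoch from k = 0 with no cap, so the
regularizer is gentle early and dominant late; ℓ2 covers all raw parameter
groups including `φ`'s log-parameter. Holdout genes are dropped from the
high-resolution loss (and from `φ`'s parameterization) but keep their `Q`
columns in the low-resolution term, which is what makes them imputable.

### Defaults and their rationale

| parameter | default | why |
|---|---|---|
| learning rate | 0.05 | works across the count scales tested; aggressive but stabilized by Adam |
| epochs | 5000 | fixed budget, no early stopping; the schedule ω is tied to epoch count |
| restarts | 3 | NMF is initialization-sensitive; best final loss wins |
| ℓ2 weight | 1e-5 | numerical stabilizer on raw parameters, not a sparsity prior |
| λ (entropy) | none; 1000 suggested for imputation, 500 for deconvolution | imputation wants the Poisson terms dominant; deconvolution wants near-one-hot `P` late in training |
| mean floor | 1e-8 | floors only the log argument so the loss stays finite when a mean underflows; the linear term is exact |
| initialization | Normal(0, 0.1) on logits/log-params, restart r seeded seed+r | small perturbations around the uniform/unit point; bitwise reproducible |

## Synthetic data generator

The generator emulates a paired-slice study end to end: high-resolution
spots uniform in a 1 mm² field; cell types assigned by an l×l checkerboard
over the bounding box with type `(r+c) mod h`, which guarantees edge-adjacent
grids always differ for any h ≥ 2; per-spot UMI totals Gamma-distributed
(shape 4) around `base_umi` = 150, a typical targeted-panel per-cell
transcript count; a coverage fraction ρ scaling every total to emulate
sequencing depth; counts Poisson-sampled from row-stochastic cell-type
profiles; and the low-resolution slice formed by exact integer summation of
mapped spots (count conservation is an identity). Profiles are symmetric
Dirichlet draws (concentration 0.3, resampled if any pair has cosine
similarity ≥ 0.95) standing in for measured cell-type signatures. The
simulated mapping sends every spot to its nearest low-resolution lattice
site with no cutoff so the whole slice is aggregated; a cutoff can be
reinstated via `mapping_max_dist`. Ground-truth low-resolution mixtures
weight each mapped spot's type by its expected total (ρ·UMI), matching the
count-mass meaning of `M`.

What the generator does *not* emulate: platform-specific capture efficiency
differences (the two slices share one latent mean, so φ's benefit is not
exercised), segmentation errors, misregistered mappings, overdispersion or
zero inflation, and tissue-realistic morphology. Passing tests therefore
demonstrate correct inference under the model's own assumptions, not
robustness to real cross-platform artifacts.

The standard study conditions used in the tests and the acceptance script
are a 4×4 checkerboard with h = 3 types, 60 high-resolution spots, 12
low-resolution spots, 30 genes with a 20-gene panel, ρ ∈ {0.25, 1, 2};
fits use 2000 epochs (1500 with 2 restarts for the coverage sweep) so the
whole suite runs in about a minute on one CPU while leaving the qualitative
ordering of every comparison unchanged from longer runs.

## Evaluation protocol

The holdout protocol splits the panel into n near-equal folds (seeded
shuffle, round-robin); each fold is hidden from the high-resolution loss,
refit, imputed, and every gene scored by the squared Pearson correlation
`cov²(x,y)/(σ²_x σ²_y)` against the held-out observed counts. A constant
vector (e.g. an all-zero holdout gene) has undefined correlation; it scores
0 and is flagged rather than raising, so fold aggregation never aborts. A
fold equal to the whole panel is rejected: it would leave no
high-resolution signal at all.

Mapping-only baselines provide the floor: variant A splits the mapped
low-resolution spot's counts equally among its spots (mass-conserving — the
natural reading where the alternative, copying, would inflate totals);
variant B splits proportionally to each spot's total observed panel count;
variants C/D smooth A/B by averaging over the k = 10 spatially nearest
spots (self included).

Deconvolution is scored per low-resolution spot by Jensen–Shannon
divergence (natural log, bounded by ln 2) between predicted and true
mixtures, after matching latent factors to true types greedily on the
cosine-similarity matrix of the hard assignments. ARI is computed from the
standard pair-counting contingency formula and cross-checked against
scikit-learn in the tests.

## Numerical choices and degenerate inputs

- Row-stochasticity of `P`/`Q` is exact up to softmax arithmetic (~1e-16);
  the contract is stated at 1e-6.
- `argmax` ties (hard assignment, fold argmax) break to the lowest index.
- `raw_to_scaled` on a zero spot row returns `N = 0` with a uniform `P` row;
  an all-zero factor expression row is an error (the factor is meaningless).
- Empty low-resolution spots (no mapped spots) deconvolve to an all-zero
  row plus a flag instead of NaNs.
- A non-finite training loss raises immediately, naming the epoch.

## Known limitations

- Poisson likelihood only; no overdispersion or zero inflation.
- The mapping is taken as given and trusted; noise in `Γ` propagates
  directly into `M`'s support.
- `h` is a config knob; no model selection is provided.
- The dense working arrays in the trainer are sized for panel-scale
  problems (10²–10⁴ spots, 10¹–10³ genes), not whole-transcriptome ones.
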