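"""Holdout evaluation, mapping-based baselines, and agreement metrics.

The imputation protocol splits the high-resolution gene panel into folds;
for each fold the model is refit with those genes held out of the
high-resolution loss, the fold genes are imputed, and each gene is scored
by the squared Pearson correlation against the observed (held-out)
counts.  Deconvolution is scored per low-resolution spot by
Jensen-Shannon divergence against true mixture proportions, and hard
assignments by cosine-similarity matrices and the adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.special import rel_entr

from .data_io import PairedData
from .model import FittedModel, ModelConfig, fit, impute

__all__ = [
    "HoldoutScheme",
    "EvaluationResult",
    "r2_score",
    "js_divergence",
    "make_folds",
    "holdout_evaluate",
    "baseline_impute",
    "cosine_similarity_matrix",
    "adjusted_rand_index",
    "match_factors",
]


class EvaluationError(ValueError):
    pass


@dataclass
class HoldoutScheme:
    """Disjoint gene folds covering the high-resolution panel."""

    folds: list[list[str]]
    seed: int = 0

    def __post_init__(self) -> None:
        flat = [g for fold in self.folds for g in fold]
        if len(flat) != len(set(flat)):
            raise EvaluationError("folds are not pairwise disjoint")
        sizes = [len(f) for f in self.folds]
        if sizes and max(sizes) - min(sizes) > 1:
            raise EvaluationError("fold sizes differ by more than 1")

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def genes(self) -> set[str]:
        return {g for fold in self.folds for g in fold}


@dataclass
class EvaluationResult:
    """Per-gene holdout R-squared scores and their mean, plus optional JS."""

    per_gene_r2: dict[str, float]
    mean_r2: float
    method_label: str
    per_spot_js: np.ndarray | None = None
    mean_js: float | None = None
    degenerate_genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def r2_score(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation cov(x, y)^2 / (var(x) var(y)).

    Symmetric, affine-invariant, in [0, 1].  If either vector is constant
    the correlation is undefined; 0.0 is returned so fold aggregation
    never aborts on an all-zero holdout gene (callers may track such
    genes via :func:`is_degenerate_pair`).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise EvaluationError("r2_score needs two equal-length vectors, length >= 2")
    if is_degenerate_pair(x, y):
        return 0.0
    xc = x - x.mean()
    yc = y - y.mean()
    cov = float(xc @ yc)
    return min(1.0, cov * cov / (float(xc @ xc) * float(yc @ yc)))


def is_degenerate_pair(x: np.ndarray, y: np.ndarray) -> bool:
    """True when either vector is constant (zero variance)."""
    return bool(np.ptp(x) == 0 or np.ptp(y) == 0)


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence, natural log: in [0, ln 2], 0 iff p == q.

    Inputs are nonnegative vectors summing to ~1 (renormalized exactly).
    """
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.shape != q.shape:
        raise EvaluationError("js_divergence needs equal-length vectors")
    if p.min() < 0 or q.min() < 0:
        raise EvaluationError("js_divergence inputs must be nonnegative")
    ps, qs = p.sum(), q.sum()
    if ps <= 0 or qs <= 0:
        raise EvaluationError("js_divergence inputs must have positive mass")
    if abs(ps - 1) > 1e-6 or abs(qs - 1) > 1e-6:
        raise EvaluationError("js_divergence inputs must sum to 1 within 1e-6")
    p, q = p / ps, q / qs
    m = 0.5 * (p + q)
    return float(0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum())


def cosine_similarity_matrix(
    labels_a: np.ndarray, labels_b: np.ndarray
) -> np.ndarray:
    """Cosine similarity between the indicator vectors of two labelings.

    Entry (t, f) is the cosine between the binary membership vector of
    label t in ``labels_a`` and label f in ``labels_b``; an empty class
    yields a zero row/column.
    """
    a = np.asarray(labels_a, dtype=int).ravel()
    b = np.asarray(labels_b, dtype=int).ravel()
    if a.shape != b.shape:
        raise EvaluationError("labelings must have equal length")
    vals_a = np.unique(a)
    vals_b = np.unique(b)
    out = np.zeros((vals_a.size, vals_b.size))
    for i, t in enumerate(vals_a):
        ind_a = a == t
        na = np.sqrt(ind_a.sum())
        for j, f in enumerate(vals_b):
            ind_b = b == f
            nb = np.sqrt(ind_b.sum())
            if na > 0 and nb > 0:
                out[i, j] = (ind_a & ind_b).sum() / (na * nb)
    return out


def adjusted_rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    Computed from the contingency table: 1 for identical partitions,
    about 0 for independent ones.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise EvaluationError("labelings must have equal length")
    if a.size < 2:
        raise EvaluationError("need at least two items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(table, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(a.size)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))


def match_factors(cos_matrix: np.ndarray) -> dict[int, int]:
    """Greedy one-to-one matching on a similarity matrix (rows -> columns).

    Repeatedly takes the globally largest remaining entry.  Used to pair
    latent factors with ground-truth types before scoring.
    """
    sim = np.array(cos_matrix, dtype=float)
    mapping: dict[int, int] = {}
    n = min(sim.shape)
    for _ in range(n):
        i, j = np.unravel_index(np.argmax(sim), sim.shape)
        mapping[int(i)] = int(j)
        sim[i, :] = -np.inf
        sim[:, j] = -np.inf
    return mapping


# ---------------------------------------------------------------------------
# Holdout protocol
# ---------------------------------------------------------------------------

def make_folds(panel: list[str], n_folds: int = 10, seed: int = 0) -> HoldoutScheme:
    """Split the panel into near-equal folds by seeded shuffle + round robin."""
    if n_folds > len(panel):
        raise EvaluationError(
            f"n_folds={n_folds} exceeds panel size {len(panel)}"
        )
    if n_folds < 1:
        raise EvaluationError("n_folds must be >= 1")
    rng = np.random.default_rng(seed)
    shuffled = sorted(panel)
    rng.shuffle(shuffled)
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for i, g in enumerate(shuffled):
        folds[i % n_folds].append(g)
    return HoldoutScheme(folds=folds, seed=seed)


def holdout_evaluate(
    data: PairedData,
    config: ModelConfig,
    scheme: HoldoutScheme,
    method_label: str = "model",
) -> EvaluationResult:
    """Fit once per fold with the fold held out; score imputed vs observed.

    Each panel gene is a holdout exactly once; its imputed high-res
    expression is scored by :func:`r2_score` against the observed counts
    that the fit never saw.  The summary is the arithmetic mean over all
    panel genes.
    """
    panel = set(data.panel)
    if scheme.genes != panel:
        raise EvaluationError("scheme does not cover exactly the high-res panel")
    observed = np.asarray(data.xenium.counts.todense())
    gene_col = {g: k for k, g in enumerate(data.xenium.gene_names)}
    per_gene: dict[str, float] = {}
    degenerate: list[str] = []
    for fold_idx, fold in enumerate(scheme.folds):
        if set(fold) == panel:
            raise EvaluationError(
                f"fold {fold_idx} holds out the entire panel: no "
                "high-resolution signal left to train on"
            )
        try:
            model = fit(data, config, holdout_genes=fold)
        except Exception as exc:  # annotate with the fold for diagnosis
            raise EvaluationError(f"fit failed on fold {fold_idx}: {exc}") from exc
        imputed = impute(model, fold)
        for k, g in enumerate(fold):
            obs = observed[:, gene_col[g]]
            if is_degenerate_pair(obs, imputed[:, k]):
                degenerate.append(g)
            per_gene[g] = r2_score(obs, imputed[:, k])
    mean_r2 = float(np.mean(list(per_gene.values())))
    return EvaluationResult(
        per_gene_r2=per_gene,
        mean_r2=mean_r2,
        method_label=method_label,
        degenerate_genes=degenerate,
    )


def holdout_evaluate_baseline(
    data: PairedData,
    scheme: HoldoutScheme,
    variant: str,
    k_neighbors: int = 10,
) -> EvaluationResult:
    """Score a mapping-based baseline under the same holdout protocol."""
    panel = set(data.panel)
    if scheme.genes != panel:
        raise EvaluationError("scheme does not cover exactly the high-res panel")
    observed = np.asarray(data.xenium.counts.todense())
    gene_col = {g: k for k, g in enumerate(data.xenium.gene_names)}
    per_gene: dict[str, float] = {}
    degenerate: list[str] = []
    for fold in scheme.folds:
        imputed = baseline_impute(data, variant, fold, k_neighbors=k_neighbors)
        for k, g in enumerate(fold):
            obs = observed[:, gene_col[g]]
            if is_degenerate_pair(obs, imputed[:, k]):
                degenerate.append(g)
            per_gene[g] = r2_score(obs, imputed[:, k])
    return EvaluationResult(
        per_gene_r2=per_gene,
        mean_r2=float(np.mean(list(per_gene.values()))),
        method_label=f"baseline_{variant}",
        degenerate_genes=degenerate,
    )


# ---------------------------------------------------------------------------
# Mapping-based baselines
# ---------------------------------------------------------------------------

def baseline_impute(
    data: PairedData,
    variant: str,
    genes: list[str],
    k_neighbors: int = 10,
) -> np.ndarray:
    """Impute high-res expression from the mapped low-res spot alone.

    Variants:

    - ``A``: each high-res spot receives its mapped low-res spot's count
      split equally among the spots mapped there (mass-conserving);
      unmapped spots get 0.
    - ``B``: as A, but the split is proportional to each spot's total
      observed panel count.
    - ``C`` / ``D``: the per-spot values of A / B smoothed by averaging
      over the ``k_neighbors`` spatially nearest high-res spots (self
      included, Euclidean).
    """
    variant = variant.upper()
    if variant not in {"A", "B", "C", "D"}:
        raise EvaluationError(f"unknown baseline variant {variant!r}")
    uni_pos = {g: j for j, g in enumerate(data.gene_universe)}
    missing = [g for g in genes if g not in uni_pos]
    if missing:
        raise EvaluationError(f"genes absent from the low-res slice: {missing}")
    cols = [uni_pos[g] for g in genes]
    AV = np.asarray(data.visium.counts.todense())[:, cols]
    gamma = sp.coo_matrix(data.gamma)
    n_x = data.xenium.n_spots
    mapped_spot = np.full(n_x, -1, dtype=int)
    mapped_spot[gamma.row] = gamma.col

    out = np.zeros((n_x, len(genes)))
    mapped = mapped_spot >= 0
    if variant in {"A", "C"}:
        counts_per_v = np.bincount(
            mapped_spot[mapped], minlength=data.visium.n_spots
        ).astype(float)
        share = np.zeros(n_x)
        share[mapped] = 1.0 / counts_per_v[mapped_spot[mapped]]
    else:
        totals = np.asarray(data.xenium.counts.sum(axis=1)).ravel().astype(float)
        mass_per_v = np.zeros(data.visium.n_spots)
        np.add.at(mass_per_v, mapped_spot[mapped], totals[mapped])
        share = np.zeros(n_x)
        ok = mapped & (mass_per_v[np.clip(mapped_spot, 0, None)] > 0)
        share[ok] = totals[ok] / mass_per_v[mapped_spot[ok]]
    out[mapped] = share[mapped, None] * AV[mapped_spot[mapped]]

    if variant in {"C", "D"}:
        if k_neighbors < 1:
            raise EvaluationError("k_neighbors must be >= 1")
        if k_neighbors > n_x:
            raise EvaluationError(
                f"k_neighbors={k_neighbors} exceeds number of high-res spots {n_x}"
            )
        tree = cKDTree(data.xenium.coords)
        _, nbr = tree.query(data.xenium.coords, k=k_neighbors)
        nbr = np.atleast_2d(nbr)
        if nbr.shape[0] != n_x:
            nbr = nbr.reshape(n_x, -1)
        out = out[nbr].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# Deconvolution scoring
# ---------------------------------------------------------------------------

def score_deconvolution(
    mixtures: np.ndarray,
    empty_mask: np.ndarray,
    truth_mixture: np.ndarray,
    factor_to_type: dict[int, int],
) -> tuple[np.ndarray, float]:
    """Per-spot JS divergence of matched predicted vs true mixtures.

    ``factor_to_type`` maps latent factor index to ground-truth type
    index (from :func:`match_factors`); unmatched factors' mass is
    dropped and rows renormalized.  Empty low-res spots are skipped.
    """
    n_types = truth_mixture.shape[1]
    per_spot = []
    for j in range(truth_mixture.shape[0]):
        if empty_mask[j] or truth_mixture[j].sum() <= 0:
            continue
        pred = np.zeros(n_types)
        for f, t in factor_to_type.items():
            pred[t] += mixtures[j, f]
        if pred.sum() <= 0:
            pred = np.full(n_types, 1.0 / n_types)
        else:
            pred = pred / pred.sum()
        per_spot.append(js_divergence(pred, truth_mixture[j] / truth_mixture[j].sum()))
    per_spot = np.asarray(per_spot)
    return per_spot, float(per_spot.mean()) if per_spot.size else float("nan")
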