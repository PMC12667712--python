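"""Shared Poisson NMF across a paired pair of SRT slices.

The model assumes a latent high-resolution, whole-transcriptome count
matrix A_U with Poisson mean diag(N) P Q, where N holds per-spot total
counts, P is the row-stochastic spot-to-factor assignment and Q the
row-stochastic factor expression profiles.  The observed high-resolution
slice is a column submatrix of A_U; the observed low-resolution slice is
an aggregation of mapped high-resolution spots through a nonnegative
weight matrix M supported on the spatial mapping, with an optional
gene-wise platform scaling phi on the low-resolution side:

    loss = PoiLoss(A_X; diag(N) P Q_X) + PoiLoss(A_V; M^T P Q diag(phi))
           + omega(epoch) * (-sum P log P)          [entropy, optional]
           + l2_weight * sum(raw parameters^2)

with PoiLoss(Y; Z) = sum(Z - Y log Z), the Poisson negative
log-likelihood up to a constant.  Constraints hold by construction: P and
Q are row-softmaxes of unconstrained logits; N, M and phi are
exponentials of log-parameters, with M parameterized only on the support
of the mapping and phi fixed to 1 for genes outside the trained panel.
Training is Adam on the raw parameters; the fit is restarted several
times from independent initializations and the restart with the lowest
final loss is kept.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import scipy.io
import scipy.sparse as sp
import yaml

from .data_io import PairedData

__all__ = [
    "ModelConfig",
    "FittedModel",
    "RawFactorization",
    "ModelError",
    "poisson_loss",
    "entropy_weight",
    "entropy_term",
    "total_loss",
    "fit",
    "impute",
    "deconvolve_visium",
    "assign_cell_types",
    "raw_to_scaled",
    "scaled_to_raw",
    "save_model",
    "load_model",
]

logger = logging.getLogger("srtjoint")

#: Standard deviation of the Normal(0, sigma) initialization of raw parameters.
INIT_STD = 0.1

#: Adam moment decay rates and epsilon (library-standard defaults).
ADAM_BETA1, ADAM_BETA2, ADAM_EPS = 0.9, 0.999, 1e-8


class ModelError(ValueError):
    """Raised for invalid model configuration, shapes, or failed training."""


@dataclass
class ModelConfig:
    """Hyperparameters of the paired factorization.

    Parameters
    ----------
    h
        Number of latent factors (intended cell types).
    lambda_entropy
        Entropy-schedule scale lambda, or ``None`` to disable the entropy
        term.  The entropy weight grows as exp(epoch / lambda), so smaller
        lambda pushes harder toward one-hot spot assignments late in
        training.  Typical values: 1000 when imputing, 500 when
        deconvolving.
    learning_rate, epochs, restarts
        Adam step size (default 0.05), number of training epochs (default
        5000) and number of random restarts (default 3; the best final
        loss wins).
    l2_weight
        Ridge penalty on the raw (pre-softmax / pre-exponential)
        parameters, default 1e-5.
    platform_scaling
        Learn a gene-wise multiplier phi on the low-resolution mean to
        absorb platform capture-efficiency differences.  phi is fixed at 1
        for genes outside the trained high-res panel.
    mean_floor
        Floor inside the Poisson log to keep the loss finite when a
        reconstructed mean underflows; applied to the log argument only.
    """

    h: int
    lambda_entropy: float | None = None
    learning_rate: float = 0.05
    epochs: int = 5000
    restarts: int = 3
    l2_weight: float = 1e-5
    platform_scaling: bool = False
    seed: int = 0
    mean_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.h < 1:
            raise ModelError("h must be >= 1")
        if self.epochs < 1:
            raise ModelError("epochs must be >= 1")
        if self.restarts < 1:
            raise ModelError("restarts must be >= 1")
        if self.l2_weight < 0:
            raise ModelError("l2_weight must be >= 0")
        if self.lambda_entropy is not None and self.lambda_entropy <= 0:
            raise ModelError("lambda_entropy must be positive or None")
        if self.learning_rate <= 0:
            raise ModelError("learning_rate must be positive")
        if self.mean_floor <= 0:
            raise ModelError("mean_floor must be positive")


@dataclass
class RawFactorization:
    """Unconstrained three-factor form: means W @ H, aggregation weights K."""

    W: np.ndarray  # |S_X| x h, nonnegative
    H: np.ndarray  # h x |G|, nonnegative
    K: np.ndarray  # |S_X| x |S_V|, nonnegative, supported on the mapping

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        for name, arr in (("W", self.W), ("H", self.H), ("K", self.K)):
            if arr.size and arr.min() < 0:
                raise ModelError(f"{name} has negative entries")


@dataclass
class FittedModel:
    """Result of :func:`fit`: count-scaled factors plus training metadata."""

    P: np.ndarray                 # |S_X| x h, rows sum to 1
    Q: np.ndarray                 # h x |G_universe|, rows sum to 1
    N: np.ndarray                 # |S_X|, positive
    M: sp.csr_matrix              # |S_X| x |S_V|, support within the mapping
    phi: np.ndarray               # |G_universe|, 1 off the trained panel
    trained_gene_mask: np.ndarray  # bool over gene_universe
    gene_universe: list[str]
    final_loss: float
    loss_history: np.ndarray
    restart_losses: np.ndarray
    config: ModelConfig
    raw_params: dict = field(default_factory=dict, repr=False)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_universe.index(gene)
        except ValueError:
            raise ModelError(f"unknown gene: {gene!r}") from None


# ---------------------------------------------------------------------------
# Loss components
# ---------------------------------------------------------------------------

def poisson_loss(Y: np.ndarray, Z: np.ndarray, mean_floor: float = 1e-8) -> float:
    """Poisson negative log-likelihood sum(Z - Y log Z), up to a constant.

    The log argument is floored at ``mean_floor`` so the value stays
    finite when a mean entry underflows; the linear term is not floored.
    """
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if Y.shape != Z.shape:
        raise ModelError(f"shape mismatch: {Y.shape} vs {Z.shape}")
    if np.isnan(Y).any() or np.isnan(Z).any():
        raise ModelError("NaN in Poisson loss inputs")
    if Y.size and (Y.min() < 0 or Z.min() < 0):
        raise ModelError("Poisson loss inputs must be nonnegative")
    return float(np.sum(Z - Y * np.log(np.maximum(Z, mean_floor))))


def entropy_weight(epoch: int, lambda_entropy: float) -> float:
    """Schedule weight omega = exp(epoch / lambda); 1 at epoch 0, increasing."""
    if lambda_entropy <= 0:
        raise ModelError("lambda_entropy must be positive")
    if epoch < 0:
        raise ModelError("epoch must be nonnegative")
    return float(np.exp(epoch / lambda_entropy))


def entropy_term(P: np.ndarray) -> float:
    """Unweighted entropy -sum(P log P) of a row-stochastic matrix.

    Zero exactly when every row is one-hot; 0 * log 0 is taken as 0.
    """
    P = np.asarray(P, dtype=float)
    if P.size and P.min() < 0:
        raise ModelError("P has negative entries")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(np.where(P > 0, P, 1.0)), 0.0)
    return float(-plogp.sum())


def _dense(mat) -> np.ndarray:
    return np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)


def total_loss(
    data: PairedData,
    *,
    N: np.ndarray,
    P: np.ndarray,
    Q: np.ndarray,
    M,
    phi: np.ndarray | None = None,
    trained_gene_mask: np.ndarray | None = None,
    epoch: int = 0,
    lambda_entropy: float | None = None,
    l2_weight: float = 0.0,
    raw_params: dict | None = None,
    mean_floor: float = 1e-8,
) -> float:
    """Objective value for a given parameter set on a paired dataset.

    With ``lambda_entropy`` unset and ``l2_weight`` zero this is exactly
    the sum of the two Poisson terms.  The high-resolution term is
    restricted to the trained panel columns (``trained_gene_mask`` over
    the gene universe; defaults to the full panel).  The l2 term requires
    the raw parameter arrays and is skipped when they are absent.
    """
    N = np.asarray(N, dtype=float)
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    G = len(data.gene_universe)
    if Q.shape[1] != G:
        raise ModelError(f"Q has {Q.shape[1]} genes; universe has {G}")
    if P.shape[0] != data.xenium.n_spots or P.shape[1] != Q.shape[0]:
        raise ModelError("P shape inconsistent with data / Q")
    panel_idx = data.panel_indices
    if trained_gene_mask is None:
        trained_gene_mask = np.zeros(G, dtype=bool)
        trained_gene_mask[panel_idx] = True
    trained_panel_cols = [
        k for k, j in enumerate(panel_idx) if trained_gene_mask[j]
    ]
    trained_universe_cols = panel_idx[trained_panel_cols]

    AX = _dense(data.xenium.counts)[:, trained_panel_cols]
    AV = _dense(data.visium.counts)
    Md = _dense(M)

    ZX = (N[:, None] * P) @ Q[:, trained_universe_cols]
    ZV = Md.T @ (P @ Q)
    if phi is not None:
        ZV = ZV * np.asarray(phi, dtype=float)[None, :]
    loss = poisson_loss(AX, ZX, mean_floor) + poisson_loss(AV, ZV, mean_floor)
    if lambda_entropy is not None:
        loss += entropy_weight(epoch, lambda_entropy) * entropy_term(P)
    if l2_weight and raw_params:
        loss += l2_weight * sum(
            float(np.sum(np.square(v))) for v in raw_params.values()
        )
    return float(loss)


# ---------------------------------------------------------------------------
# Count-scaled reparameterization (three-factor <-> scaled form)
# ---------------------------------------------------------------------------

def raw_to_scaled(raw: RawFactorization):
    """Convert (W, H, K) into the count-scaled form (N, P, Q, M).

    Q is H row-normalized; the row mass of H moves into W, whose row sums
    become N and whose normalized rows become P; M = diag(N) K.  The
    product is preserved: diag(N) P Q == W H.  A zero row of W yields
    N = 0 with a uniform P row.
    """
    W, H, K = raw.W, raw.H, raw.K
    h_sums = H.sum(axis=1)
    if np.any(h_sums <= 0):
        bad = np.flatnonzero(h_sums <= 0).tolist()
        raise ModelError(f"factor(s) {bad} have all-zero expression rows")
    Q = H / h_sums[:, None]
    W_scaled = W * h_sums[None, :]
    N = W_scaled.sum(axis=1)
    P = np.empty_like(W_scaled)
    pos = N > 0
    P[pos] = W_scaled[pos] / N[pos, None]
    P[~pos] = 1.0 / W.shape[1]
    M = N[:, None] * K
    return N, P, Q, M


def scaled_to_raw(N, P, Q, M) -> RawFactorization:
    """Inverse of :func:`raw_to_scaled` up to the product W H = diag(N) P Q."""
    N = np.asarray(N, dtype=float)
    Md = _dense(M)
    W = N[:, None] * np.asarray(P, dtype=float)
    K = np.empty_like(Md)
    pos = N > 0
    K[pos] = Md[pos] / N[pos, None]
    K[~pos] = 0.0
    return RawFactorization(W=W, H=np.asarray(Q, dtype=float), K=K)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _softmax_rows_backward(P: np.ndarray, dP: np.ndarray) -> np.ndarray:
    inner = (dP * P).sum(axis=1, keepdims=True)
    return P * (dP - inner)


@dataclass
class _Problem:
    """Dense working arrays for one fit (tiny relative to training cost)."""

    AX: np.ndarray            # |S_X| x |trained panel|
    AV: np.ndarray            # |S_V| x |G|
    sup_rows: np.ndarray      # mapping support, row indices
    sup_cols: np.ndarray      # mapping support, column indices
    trained_universe_cols: np.ndarray
    trained_gene_mask: np.ndarray
    n_x: int
    n_v: int
    n_genes: int


def _build_problem(data: PairedData, holdout_genes) -> _Problem:
    holdout = set(holdout_genes)
    unknown = holdout - set(data.gene_universe)
    if unknown:
        raise ModelError(f"holdout genes outside the universe: {sorted(unknown)}")
    panel_idx = data.panel_indices
    G = len(data.gene_universe)
    trained_gene_mask = np.zeros(G, dtype=bool)
    for k, g in enumerate(data.xenium.gene_names):
        if g not in holdout:
            trained_gene_mask[panel_idx[k]] = True
    trained_panel_cols = [
        k for k, g in enumerate(data.xenium.gene_names) if g not in holdout
    ]
    trained_universe_cols = panel_idx[trained_panel_cols]
    gamma = sp.coo_matrix(data.gamma)
    if len(trained_panel_cols) == 0 and gamma.nnz == 0:
        raise ModelError(
            "nothing to train on: empty trained panel and empty spatial mapping"
        )
    return _Problem(
        AX=_dense(data.xenium.counts)[:, trained_panel_cols],
        AV=_dense(data.visium.counts),
        sup_rows=gamma.row.astype(int),
        sup_cols=gamma.col.astype(int),
        trained_universe_cols=trained_universe_cols,
        trained_gene_mask=trained_gene_mask,
        n_x=data.xenium.n_spots,
        n_v=data.visium.n_spots,
        n_genes=G,
    )


def _materialize(raw: dict, prob: _Problem, cfg: ModelConfig):
    P = _softmax_rows(raw["p_logit"])
    Q = _softmax_rows(raw["q_logit"])
    N = np.exp(raw["log_n"])
    M = np.zeros((prob.n_x, prob.n_v))
    M[prob.sup_rows, prob.sup_cols] = np.exp(raw["log_m"])
    phi = np.ones(prob.n_genes)
    if cfg.platform_scaling:
        phi[prob.trained_universe_cols] = np.exp(raw["log_phi"])
    return P, Q, N, M, phi


def _poisson_grad(Y: np.ndarray, Z: np.ndarray, floor: float) -> np.ndarray:
    # d/dZ [Z - Y log(max(Z, floor))]: the log term is flat below the floor.
    return 1.0 - np.where(Z > floor, Y / np.maximum(Z, floor), 0.0)


def _loss_and_grad(raw: dict, prob: _Problem, cfg: ModelConfig, epoch: int):
    P, Q, N, M, phi = _materialize(raw, prob, cfg)
    floor = cfg.mean_floor

    dP = np.zeros_like(P)
    dQ = np.zeros_like(Q)
    dN = np.zeros_like(N)

    # High-resolution term over the trained panel columns.
    Qt = Q[:, prob.trained_universe_cols]
    Wn = N[:, None] * P
    ZX = Wn @ Qt
    loss = np.sum(ZX) - np.sum(
        prob.AX * np.log(np.maximum(ZX, floor))
    )
    GX = _poisson_grad(prob.AX, ZX, floor)
    dWn = GX @ Qt.T
    dQ[:, prob.trained_universe_cols] += Wn.T @ GX
    dN += (dWn * P).sum(axis=1)
    dP += dWn * N[:, None]

    # Low-resolution term through the mapping and platform scaling.
    B = P @ Q
    ZV0 = M.T @ B
    ZV = ZV0 * phi[None, :]
    loss += np.sum(ZV) - np.sum(prob.AV * np.log(np.maximum(ZV, floor)))
    GV = _poisson_grad(prob.AV, ZV, floor)
    GVp = GV * phi[None, :]
    dB = M @ GVp
    dP += dB @ Q.T
    dQ += P.T @ dB
    dm_sup = (B[prob.sup_rows] * GVp[prob.sup_cols]).sum(axis=1)
    dphi_full = (GV * ZV0).sum(axis=0)

    # Entropy schedule: omega(epoch) * (-sum P log P).
    if cfg.lambda_entropy is not None:
        omega = entropy_weight(epoch, cfg.lambda_entropy)
        logP = np.log(np.maximum(P, 1e-300))
        loss += omega * float(-(P * logP).sum())
        dP += omega * (-(logP + 1.0))

    grads = {
        "p_logit": _softmax_rows_backward(P, dP),
        "q_logit": _softmax_rows_backward(Q, dQ),
        "log_n": dN * N,
        "log_m": dm_sup * np.exp(raw["log_m"]),
    }
    if cfg.platform_scaling:
        phi_t = np.exp(raw["log_phi"])
        grads["log_phi"] = dphi_full[prob.trained_universe_cols] * phi_t

    if cfg.l2_weight:
        for k, v in raw.items():
            loss += cfg.l2_weight * float(np.sum(np.square(v)))
            grads[k] = grads[k] + 2.0 * cfg.l2_weight * v

    return float(loss), grads


def _init_raw(prob: _Problem, cfg: ModelConfig, rng: np.random.Generator) -> dict:
    raw = {
        "p_logit": rng.normal(0.0, INIT_STD, (prob.n_x, cfg.h)),
        "q_logit": rng.normal(0.0, INIT_STD, (cfg.h, prob.n_genes)),
        "log_n": rng.normal(0.0, INIT_STD, prob.n_x),
        "log_m": rng.normal(0.0, INIT_STD, len(prob.sup_rows)),
    }
    if cfg.platform_scaling:
        raw["log_phi"] = rng.normal(0.0, INIT_STD, len(prob.trained_universe_cols))
    return raw


def _adam_fit(raw: dict, prob: _Problem, cfg: ModelConfig):
    m = {k: np.zeros_like(v) for k, v in raw.items()}
    v = {k: np.zeros_like(val) for k, val in raw.items()}
    history = np.empty(cfg.epochs)
    lr, b1, b2 = cfg.learning_rate, ADAM_BETA1, ADAM_BETA2
    for epoch in range(cfg.epochs):
        loss, grads = _loss_and_grad(raw, prob, cfg, epoch)
        if not np.isfinite(loss):
            raise ModelError(f"non-finite loss at epoch {epoch}")
        history[epoch] = loss
        t = epoch + 1
        bias1 = 1.0 - b1**t
        bias2 = 1.0 - b2**t
        for k in raw:
            g = grads[k]
            m[k] = b1 * m[k] + (1 - b1) * g
            v[k] = b2 * v[k] + (1 - b2) * g * g
            raw[k] = raw[k] - lr * (m[k] / bias1) / (
                np.sqrt(v[k] / bias2) + ADAM_EPS
            )
        if epoch % 100 == 0:
            logger.info("epoch %d: loss %.6g", epoch, loss)
    final_loss, _ = _loss_and_grad(raw, prob, cfg, cfg.epochs - 1)
    return raw, final_loss, history


def fit(
    data: PairedData,
    config: ModelConfig,
    holdout_genes: list[str] | tuple[str, ...] = (),
) -> FittedModel:
    """Fit the paired factorization, best of ``config.restarts`` restarts.

    ``holdout_genes`` are removed from the high-resolution loss (their
    observed columns are not seen during training) but keep their Q
    columns through the low-resolution term, so they can be imputed
    afterwards.  Restart r is seeded with ``config.seed + r``; the restart
    with the lowest final loss is returned.
    """
    prob = _build_problem(data, holdout_genes)
    best = None
    restart_losses = np.empty(config.restarts)
    for r in range(config.restarts):
        rng = np.random.default_rng(config.seed + r)
        raw = _init_raw(prob, config, rng)
        raw, final_loss, history = _adam_fit(raw, prob, config)
        restart_losses[r] = final_loss
        if best is None or final_loss < best[1]:
            best = (raw, final_loss, history)
        logger.info("restart %d: final loss %.6g", r, final_loss)
    raw, final_loss, history = best
    P, Q, N, M, phi = _materialize(raw, prob, config)
    M_sparse = sp.csr_matrix(
        (M[prob.sup_rows, prob.sup_cols], (prob.sup_rows, prob.sup_cols)),
        shape=(prob.n_x, prob.n_v),
    )
    return FittedModel(
        P=P,
        Q=Q,
        N=N,
        M=M_sparse,
        phi=phi,
        trained_gene_mask=prob.trained_gene_mask,
        gene_universe=list(data.gene_universe),
        final_loss=float(final_loss),
        loss_history=history,
        restart_losses=restart_losses,
        config=config,
        raw_params=raw,
    )


# ---------------------------------------------------------------------------
# Downstream: imputation, deconvolution, assignment
# ---------------------------------------------------------------------------

def impute(model: FittedModel, genes: list[str]) -> np.ndarray:
    """Predicted high-resolution expression diag(N) P Q_g for each gene.

    The platform scaling phi is not applied: the prediction lives on the
    latent (high-resolution) scale, not the low-resolution platform scale.
    """
    cols = [model.gene_index(g) for g in genes]
    return (model.N[:, None] * model.P) @ model.Q[:, cols]


def reconstruct_mean(model: FittedModel) -> np.ndarray:
    """Full latent mean diag(N) P Q over the whole gene universe."""
    return (model.N[:, None] * model.P) @ model.Q


def deconvolve_visium(model: FittedModel) -> tuple[np.ndarray, np.ndarray]:
    """Per low-res-spot factor mixtures: rows of M^T P, normalized.

    Returns ``(mixtures, empty_mask)``; spots with no mapped
    high-resolution mass get an all-zero row and are flagged in
    ``empty_mask``.
    """
    raw = np.asarray((model.M.T @ model.P))
    mass = raw.sum(axis=1)
    empty = mass <= 0
    out = np.zeros_like(raw)
    out[~empty] = raw[~empty] / mass[~empty, None]
    return out, empty


def assign_cell_types(model: FittedModel) -> np.ndarray:
    """Hard factor assignment per high-res spot: row argmax of P (ties -> lowest)."""
    return np.argmax(model.P, axis=1)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: FittedModel, outdir: str) -> None:
    """Write a fitted model to ``outdir`` in open formats."""
    os.makedirs(outdir, exist_ok=True)
    scipy.io.mmwrite(os.path.join(outdir, "P.mtx"), sp.coo_matrix(model.P))
    scipy.io.mmwrite(os.path.join(outdir, "Q.mtx"), sp.coo_matrix(model.Q))
    scipy.io.mmwrite(os.path.join(outdir, "M.mtx"), sp.coo_matrix(model.M))
    np.savetxt(os.path.join(outdir, "N.tsv"), model.N, delimiter="\t")
    np.savetxt(os.path.join(outdir, "phi.tsv"), model.phi, delimiter="\t")
    np.savetxt(
        os.path.join(outdir, "loss_history.tsv"), model.loss_history, delimiter="\t"
    )
    np.savetxt(
        os.path.join(outdir, "restart_losses.tsv"),
        model.restart_losses,
        delimiter="\t",
    )
    with open(os.path.join(outdir, "genes.txt"), "w") as fh:
        fh.write("\n".join(model.gene_universe) + "\n")
    meta = {
        "final_loss": model.final_loss,
        "trained_gene_mask": model.trained_gene_mask.astype(int).tolist(),
        "config": {
            k: v for k, v in vars(model.config).items()
        },
    }
    with open(os.path.join(outdir, "model.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def load_model(outdir: str) -> FittedModel:
    """Read back a model written by :func:`save_model` (raw params not kept)."""
    with open(os.path.join(outdir, "model.yaml")) as fh:
        meta = yaml.safe_load(fh)
    with open(os.path.join(outdir, "genes.txt")) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    P = np.asarray(scipy.io.mmread(os.path.join(outdir, "P.mtx")).todense())
    Q = np.asarray(scipy.io.mmread(os.path.join(outdir, "Q.mtx")).todense())
    M = sp.csr_matrix(scipy.io.mmread(os.path.join(outdir, "M.mtx")))
    N = np.atleast_1d(np.loadtxt(os.path.join(outdir, "N.tsv")))
    phi = np.atleast_1d(np.loadtxt(os.path.join(outdir, "phi.tsv")))
    history = np.atleast_1d(np.loadtxt(os.path.join(outdir, "loss_history.tsv")))
    restart_losses = np.atleast_1d(
        np.loadtxt(os.path.join(outdir, "restart_losses.tsv"))
    )
    return FittedModel(
        P=P,
        Q=Q,
        N=N,
        M=M,
        phi=phi,
        trained_gene_mask=np.asarray(meta["trained_gene_mask"], dtype=bool),
        gene_universe=genes,
        final_loss=float(meta["final_loss"]),
        loss_history=history,
        restart_losses=restart_losses,
        config=ModelConfig(**meta["config"]),
    )
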