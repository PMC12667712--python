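"""Synthetic paired-slice generator with ground truth.

The generator lays high-resolution spots uniformly in a square field,
assigns each spot a pure cell type from a checkerboard spatial pattern,
draws its counts from a Poisson model with a cell-type expression profile
scaled by a per-spot UMI total times a coverage fraction rho, and forms
the low-resolution slice by aggregating the mapped high-resolution spots.
Ground truth (types, profiles, per-spot mixtures) is returned alongside
the data.

Relative to real tissue, the synthetic profiles are Dirichlet draws
rather than measured cell-type signatures, and spot geometry is a uniform
scatter over a square rather than a segmented tissue; every mechanism of
the generative model (checkerboard types, coverage scaling, mapping-based
aggregation, Poisson sampling) is the real one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .data_io import PairedData, SRTSlice, build_mapping

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "make_checkerboard",
    "make_profiles",
    "simulate_xenium",
    "simulate_visium",
    "simulate_pair",
]

#: Side length of the simulated tissue field, micrometers.
FIELD_SIZE_UM = 1000.0


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Conditions of a synthetic paired-slice study.

    ``grid_side`` is the checkerboard resolution l (grids per side),
    ``n_types`` the number of cell types h, and ``coverage`` the fraction
    rho multiplying every per-spot UMI total — the knob emulating
    sequencing depth.  ``base_umi`` is the mean per-spot UMI total before
    coverage scaling (default 150, a typical targeted-panel per-cell
    transcript count); ``profile_concentration`` is the symmetric
    Dirichlet concentration of the synthetic cell-type profiles (default
    0.3, giving sparse, well-separated signatures).
    """

    grid_side: int = 10
    n_types: int = 4
    coverage: float = 1.0
    n_genes: int = 50
    panel_size: int = 30
    n_x_spots: int = 200
    n_v_spots: int = 25
    base_umi: float = 150.0
    profile_concentration: float = 0.3
    mapping_max_dist: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel_size > self.n_genes:
            raise SimulationError("panel_size must be <= n_genes")
        if self.n_types < 2:
            raise SimulationError("n_types must be >= 2")
        if self.coverage <= 0:
            raise SimulationError("coverage must be positive")
        if self.grid_side < 1:
            raise SimulationError("grid_side must be >= 1")


@dataclass
class SimulatedTruth:
    """Ground truth of a simulated pair."""

    cell_type: np.ndarray    # per high-res spot, in [0, n_types)
    profiles: np.ndarray     # n_types x n_genes, rows sum to 1 (true Q)
    x_umi: np.ndarray        # coverage-scaled per-spot UMI totals (rho * N_X)
    v_mixture: np.ndarray    # n_v_spots x n_types, rows sum to 1 where mapped


def make_checkerboard(
    coords: np.ndarray, grid_side: int, n_types: int
) -> np.ndarray:
    """Assign cell types on a checkerboard over the coordinate bounding box.

    The bounding box is divided into ``grid_side`` x ``grid_side`` cells
    and a spot in cell (r, c) gets type (r + c) mod ``n_types``, so any
    two edge-adjacent grid cells always carry different types.
    """
    coords = np.asarray(coords, dtype=float)
    if grid_side < 1 or n_types < 2:
        raise SimulationError("need grid_side >= 1 and n_types >= 2")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = hi - lo
    if np.any(span <= 0):
        raise SimulationError("degenerate bounding box: spots collinear on an axis")
    cells = np.floor((coords - lo) / span * grid_side).astype(int)
    cells = np.clip(cells, 0, grid_side - 1)  # spots on the upper edge
    return (cells[:, 0] + cells[:, 1]) % n_types


def make_profiles(
    n_types: int,
    n_genes: int,
    concentration: float,
    seed: int,
    max_cosine: float = 0.95,
    max_tries: int = 50,
) -> np.ndarray:
    """Draw distinguishable cell-type profiles from a symmetric Dirichlet.

    Rows sum to 1.  Any pair of rows with cosine similarity at or above
    ``max_cosine`` triggers a resample (bounded by ``max_tries``) so the
    types remain separable.
    """
    if n_types < 1 or n_genes < 1:
        raise SimulationError("n_types and n_genes must be >= 1")
    if concentration <= 0:
        raise SimulationError("concentration must be positive")
    rng = np.random.default_rng(seed)
    if n_genes == 1:
        return np.ones((n_types, 1))
    for _ in range(max_tries):
        profiles = rng.dirichlet(np.full(n_genes, concentration), size=n_types)
        norms = np.linalg.norm(profiles, axis=1)
        cos = (profiles @ profiles.T) / np.outer(norms, norms)
        np.fill_diagonal(cos, 0.0)
        if n_types == 1 or cos.max() < max_cosine:
            return profiles
    raise SimulationError(
        f"could not draw {n_types} distinguishable profiles in {max_tries} tries"
    )


def simulate_xenium(
    cell_type: np.ndarray,
    profiles: np.ndarray,
    x_umi: np.ndarray,
    coverage: float,
    panel: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson-sample high-res counts; return (all genes, panel restriction).

    Spot i's latent counts over all genes are Poisson with mean
    ``coverage * x_umi[i] * profiles[cell_type[i]]``, so its expected
    total is ``coverage * x_umi[i]``.  ``panel_counts`` is the column
    restriction to the targeted panel.
    """
    if coverage <= 0:
        raise SimulationError("coverage must be positive")
    cell_type = np.asarray(cell_type, dtype=int)
    x_umi = np.asarray(x_umi, dtype=float)
    if cell_type.shape[0] != x_umi.shape[0]:
        raise SimulationError("cell_type and x_umi lengths differ")
    rng = np.random.default_rng(seed)
    means = coverage * x_umi[:, None] * profiles[cell_type]
    latent = rng.poisson(means)
    panel = np.asarray(panel, dtype=int)
    return latent, latent[:, panel]


def simulate_visium(latent_counts: np.ndarray, gamma: sp.spmatrix) -> np.ndarray:
    """Aggregate mapped high-res latent counts into low-res spot counts.

    Exact integer summation: low-res spot j receives the sum of latent
    counts of all high-res spots mapped to it, conserving total counts of
    mapped spots.
    """
    latent_counts = np.asarray(latent_counts)
    gamma = sp.csr_matrix(gamma)
    if gamma.shape[0] != latent_counts.shape[0]:
        raise SimulationError(
            f"gamma has {gamma.shape[0]} rows but latent counts "
            f"{latent_counts.shape[0]}"
        )
    return np.asarray((gamma.T @ latent_counts))


def simulate_pair(config: SimulationConfig) -> tuple[PairedData, SimulatedTruth]:
    """Generate a full paired dataset plus ground truth from one config.

    High-res spots are uniform in a square field; low-res spots sit on a
    regular lattice covering the same field.  The mapping sends each
    high-res spot to its nearest low-res spot (no distance cutoff by
    default, so counts are conserved across the whole slice; set
    ``mapping_max_dist`` to reinstate a cutoff).  The true per-low-res-spot
    mixture weights each mapped spot's type by its expected total count.
    """
    rng = np.random.default_rng(config.seed)
    x_coords = rng.uniform(0.0, FIELD_SIZE_UM, size=(config.n_x_spots, 2))

    # Low-res lattice: smallest near-square grid holding n_v_spots sites.
    ncols = int(np.ceil(np.sqrt(config.n_v_spots)))
    nrows = int(np.ceil(config.n_v_spots / ncols))
    xs = (np.arange(ncols) + 0.5) * FIELD_SIZE_UM / ncols
    ys = (np.arange(nrows) + 0.5) * FIELD_SIZE_UM / nrows
    grid = np.array([(x, y) for y in ys for x in xs])[: config.n_v_spots]

    max_dist = (
        config.mapping_max_dist
        if config.mapping_max_dist is not None
        else 2.0 * FIELD_SIZE_UM  # covers the field: every spot maps
    )
    gamma = build_mapping(x_coords, grid, max_dist=max_dist)

    cell_type = make_checkerboard(x_coords, config.grid_side, config.n_types)
    profiles = make_profiles(
        config.n_types,
        config.n_genes,
        config.profile_concentration,
        seed=config.seed + 1,
    )
    # Per-spot UMI totals: Gamma-distributed around base_umi (right-skewed,
    # strictly positive, mimicking per-cell transcript-count variation).
    n_x = rng.gamma(shape=4.0, scale=config.base_umi / 4.0, size=config.n_x_spots)
    panel = rng.choice(config.n_genes, size=config.panel_size, replace=False)
    panel.sort()
    latent, panel_counts = simulate_xenium(
        cell_type, profiles, n_x, config.coverage, panel, seed=config.seed + 2
    )
    v_counts = simulate_visium(latent, gamma)

    gene_names = [f"g{j:04d}" for j in range(config.n_genes)]
    panel_names = [gene_names[j] for j in panel]
    xen = SRTSlice(
        counts=sp.csr_matrix(panel_counts),
        coords=x_coords,
        gene_names=panel_names,
        spot_ids=[f"x{i}" for i in range(config.n_x_spots)],
    )
    vis = SRTSlice(
        counts=sp.csr_matrix(v_counts),
        coords=grid,
        gene_names=gene_names,
        spot_ids=[f"v{j}" for j in range(config.n_v_spots)],
    )
    universe = panel_names + [g for g in gene_names if g not in set(panel_names)]
    data = PairedData(
        xenium=xen,
        visium=vis.subset_genes(universe),
        gamma=gamma,
        gene_universe=universe,
    )

    # True mixtures: expected count mass (rho * umi) of mapped spots per type.
    x_umi_scaled = config.coverage * n_x
    mix = np.zeros((config.n_v_spots, config.n_types))
    gamma_coo = sp.coo_matrix(gamma)
    np.add.at(mix, (gamma_coo.col, cell_type[gamma_coo.row]), x_umi_scaled[gamma_coo.row])
    mass = mix.sum(axis=1)
    mix[mass > 0] /= mass[mass > 0, None]

    # Reorder truth profiles onto the universe gene order.
    order = [gene_names.index(g) for g in universe]
    truth = SimulatedTruth(
        cell_type=cell_type,
        profiles=profiles[:, order],
        x_umi=x_umi_scaled,
        v_mixture=mix,
    )
    return data, truth
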