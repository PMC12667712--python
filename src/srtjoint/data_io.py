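"""Reading, writing and pairing of spatially resolved transcriptomics slices.

A slice is a count matrix over spots x genes together with 2-D spot
coordinates in micrometers.  Two slices of the same tissue — one
high-resolution with a targeted gene panel ("xenium" role), one
low-resolution whole-transcriptome ("visium" role) — are paired through a
binary spot-to-spot mapping built from shared, pre-registered coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.spatial.distance import cdist

__all__ = [
    "SRTSlice",
    "PairedData",
    "read_slice",
    "write_slice",
    "build_mapping",
    "align_panels",
    "read_mapping",
    "write_mapping",
]

#: Default nearest-spot matching cutoff in micrometers.
DEFAULT_MAX_DIST = 100.0


class DataValidationError(ValueError):
    """Structured validation failure naming the offending axis or genes."""


@dataclass
class SRTSlice:
    """One platform's measurement: counts, coordinates and gene names.

    Attributes
    ----------
    counts
        Nonnegative integer count matrix, spots x genes, stored sparse (CSR).
    coords
        Spot coordinates in micrometers, spots x 2.
    gene_names
        Ordered, unique gene identifiers (columns of ``counts``).
    spot_ids
        Ordered spot identifiers (rows of ``counts``).
    """

    counts: sp.csr_matrix
    coords: np.ndarray
    gene_names: list[str]
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_names = list(self.gene_names)
        self.spot_ids = list(self.spot_ids)
        n_spots, n_genes = self.counts.shape
        if self.counts.nnz and self.counts.data.min() < 0:
            raise DataValidationError("counts contain negative entries")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise DataValidationError(
                f"coords must be (spots, 2); got {self.coords.shape}"
            )
        if self.coords.shape[0] != n_spots:
            raise DataValidationError(
                f"spot axis mismatch: counts have {n_spots} rows but coords "
                f"have {self.coords.shape[0]}"
            )
        if len(self.spot_ids) != n_spots:
            raise DataValidationError(
                f"spot axis mismatch: counts have {n_spots} rows but "
                f"{len(self.spot_ids)} spot ids given"
            )
        if len(self.gene_names) != n_genes:
            raise DataValidationError(
                f"gene axis mismatch: counts have {n_genes} columns but "
                f"{len(self.gene_names)} gene names given"
            )
        if len(set(self.gene_names)) != n_genes:
            raise DataValidationError("gene names are not unique")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes: list[str]) -> "SRTSlice":
        """Return a copy restricted to ``genes``, columns in that order."""
        idx = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise DataValidationError(f"genes absent from slice: {missing}")
        cols = [idx[g] for g in genes]
        return replace(
            self, counts=self.counts[:, cols].tocsr(), gene_names=list(genes)
        )


@dataclass
class PairedData:
    """Two slices of the same tissue plus their spot-to-spot mapping.

    ``gamma`` is binary, high-res spots x low-res spots, with at most one
    nonzero per row: each high-resolution spot contributes to at most one
    low-resolution spot.  ``gene_universe`` is the ordered gene list used
    for modeling; the high-resolution panel occupies its leading positions.
    """

    xenium: SRTSlice
    visium: SRTSlice
    gamma: sp.csr_matrix
    gene_universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gamma = sp.csr_matrix(self.gamma)
        if not self.gene_universe:
            self.gene_universe = list(self.visium.gene_names)
        x_set = set(self.xenium.gene_names)
        v_set = set(self.visium.gene_names)
        missing = sorted(x_set - v_set)
        if missing:
            raise DataValidationError(
                f"high-res panel genes absent from low-res slice: {missing}"
            )
        if self.gamma.shape != (self.xenium.n_spots, self.visium.n_spots):
            raise DataValidationError(
                f"gamma shape {self.gamma.shape} does not match "
                f"({self.xenium.n_spots}, {self.visium.n_spots})"
            )
        if self.gamma.nnz:
            if not np.all(np.isin(self.gamma.data, [0, 1])):
                raise DataValidationError("gamma entries must be 0/1")
            row_nnz = np.diff(self.gamma.indptr)
            if row_nnz.max(initial=0) > 1:
                raise DataValidationError(
                    "gamma rows must have at most one nonzero"
                )

    @property
    def panel(self) -> list[str]:
        """Gene panel of the high-resolution slice."""
        return list(self.xenium.gene_names)

    @property
    def panel_indices(self) -> np.ndarray:
        """Positions of the high-res panel genes within ``gene_universe``."""
        pos = {g: i for i, g in enumerate(self.gene_universe)}
        return np.array([pos[g] for g in self.xenium.gene_names], dtype=int)


# ---------------------------------------------------------------------------
# File formats: matrix-market / delimited-text readers and writers
# ---------------------------------------------------------------------------

def _read_matrix(path: str) -> sp.csr_matrix:
    if str(path).endswith(".mtx"):
        mat = scipy.io.mmread(path)
        return sp.csr_matrix(mat)
    arr = np.loadtxt(path, ndmin=2)
    return sp.csr_matrix(arr)


def _read_coords(path: str) -> tuple[list[str], np.ndarray]:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"spot_id", "x", "y"}
    if not required.issubset(df.columns):
        raise DataValidationError(
            f"coordinate table must have columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    return df["spot_id"].astype(str).tolist(), df[["x", "y"]].to_numpy(float)


def _read_genes(path: str) -> list[str]:
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return genes


def read_slice(counts_path: str, coords_path: str, genes_path: str) -> SRTSlice:
    """Read one slice from a counts matrix, coordinate table and gene list.

    Counts may be matrix-market (``.mtx``) or whitespace-delimited dense
    text; coordinates are a TSV/CSV with columns ``spot_id, x, y``; genes
    are one name per line.  All cross-file dimensions are validated.
    """
    counts = _read_matrix(counts_path)
    spot_ids, coords = _read_coords(coords_path)
    genes = _read_genes(genes_path)
    return SRTSlice(counts=counts, coords=coords, gene_names=genes, spot_ids=spot_ids)


def write_slice(
    slc: SRTSlice, counts_path: str, coords_path: str, genes_path: str
) -> None:
    """Write a slice in the formats :func:`read_slice` accepts (lossless)."""
    scipy.io.mmwrite(counts_path, sp.coo_matrix(_as_int(slc.counts)), field="integer")
    sep = "," if str(coords_path).endswith(".csv") else "\t"
    pd.DataFrame(
        {"spot_id": slc.spot_ids, "x": slc.coords[:, 0], "y": slc.coords[:, 1]}
    ).to_csv(coords_path, sep=sep, index=False)
    with open(genes_path, "w") as fh:
        fh.write("\n".join(slc.gene_names) + "\n")


def _as_int(mat: sp.spmatrix) -> sp.spmatrix:
    """Cast an integral-valued sparse matrix to an integer dtype."""
    if np.issubdtype(mat.dtype, np.integer):
        return mat
    out = mat.astype(np.int64)
    if (out != mat).nnz:
        raise DataValidationError("count matrix has non-integer entries")
    return out


# ---------------------------------------------------------------------------
# Spatial mapping
# ---------------------------------------------------------------------------

def build_mapping(
    x_coords: np.ndarray,
    v_coords: np.ndarray,
    max_dist: float = DEFAULT_MAX_DIST,
) -> sp.csr_matrix:
    """Map each high-res spot to its nearest low-res spot within ``max_dist``.

    Returns a binary sparse matrix with entry (i, j) = 1 iff low-res spot j
    is the Euclidean-nearest to high-res spot i and lies within ``max_dist``
    micrometers.  Ties go to the lowest low-res index; rows whose nearest
    spot is too far are left empty.
    """
    x_coords = np.asarray(x_coords, dtype=float)
    v_coords = np.asarray(v_coords, dtype=float)
    if x_coords.size == 0 or v_coords.size == 0:
        raise DataValidationError("coordinate sets must be nonempty")
    if max_dist <= 0:
        raise DataValidationError("max_dist must be positive")
    dists = cdist(x_coords, v_coords)
    nearest = np.argmin(dists, axis=1)  # argmin takes the lowest index on ties
    in_range = dists[np.arange(len(nearest)), nearest] <= max_dist
    rows = np.flatnonzero(in_range)
    cols = nearest[in_range]
    gamma = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(x_coords.shape[0], v_coords.shape[0]),
    )
    return gamma


def write_mapping(gamma: sp.spmatrix, path: str) -> None:
    """Write the mapping as a 3-column triplet TSV with an index-base header."""
    coo = sp.coo_matrix(gamma)
    with open(path, "w") as fh:
        fh.write(f"# shape={coo.shape[0]}x{coo.shape[1]} index_base=0\n")
        fh.write("x_index\tv_index\tvalue\n")
        for i, j in zip(coo.row, coo.col):
            fh.write(f"{i}\t{j}\t1\n")


def read_mapping(path: str) -> sp.csr_matrix:
    """Read a mapping written by :func:`write_mapping`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise DataValidationError("mapping file missing shape header")
        fields = dict(tok.split("=") for tok in header[1:].split())
        nx, nv = (int(s) for s in fields["shape"].split("x"))
        base = int(fields.get("index_base", 0))
        df = pd.read_csv(fh, sep="\t")
    rows = df["x_index"].to_numpy(int) - base
    cols = df["v_index"].to_numpy(int) - base
    return sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(nx, nv))


# ---------------------------------------------------------------------------
# Gene-panel alignment
# ---------------------------------------------------------------------------

def align_panels(
    xenium: SRTSlice,
    visium: SRTSlice,
    gamma: sp.spmatrix,
    gene_universe: list[str] | None = None,
) -> PairedData:
    """Pair two slices, reordering columns onto a shared gene universe.

    Gene matching is case-sensitive exact string equality.  The universe
    defaults to the high-res panel (which must be contained in the low-res
    panel); extra low-res genes may be requested explicitly, e.g. as
    imputation targets.  The high-res panel genes occupy the leading
    universe positions, in the high-res slice's order.
    """
    x_genes = list(xenium.gene_names)
    v_set = set(visium.gene_names)
    missing = [g for g in x_genes if g not in v_set]
    if missing:
        raise DataValidationError(
            f"high-res panel genes absent from low-res slice: {missing}"
        )
    if gene_universe is None:
        universe = list(x_genes)
    else:
        extra_missing = [g for g in gene_universe if g not in v_set]
        if extra_missing:
            raise DataValidationError(
                f"requested universe genes absent from low-res slice: {extra_missing}"
            )
        extras = [g for g in gene_universe if g not in set(x_genes)]
        universe = list(x_genes) + extras
    return PairedData(
        xenium=xenium,
        visium=visium.subset_genes(universe),
        gamma=sp.csr_matrix(gamma),
        gene_universe=universe,
    )
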