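"""Readers for spatial transcriptomic datasets.

Three on-disk layouts are supported:

``mtx_dir``
    A directory in the CellRanger style: ``matrix.mtx`` (or ``matrix.mtx.gz``,
    genes × spots, MatrixMarket), ``barcodes.tsv``, ``features.tsv`` or
    ``genes.tsv``, plus a positions table (``positions.csv``/``.tsv`` with
    columns ``spot_id``, ``x``, ``y``).
``h5_container``
    An AnnData ``.h5ad`` file with counts in ``X`` and coordinates in
    ``obsm["spatial"]``.
``csv``
    A directory with a dense ``counts.csv`` (header row = gene ids, first
    column = spot id) and ``coords.csv`` (``spot_id``, ``x``, ``y``).

Counts and coordinates are aligned on spot identifiers; the coordinate table
is reordered to the count matrix order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class AlignmentError(ValueError):
    """Spot identifiers of counts and coordinates do not match."""


@dataclass
class ExpressionMatrix:
    """Spot × gene expression values with identifiers.

    ``layer`` records whether ``values`` are raw counts or
    library-size-normalized log values.
    """

    values: np.ndarray | sp.spmatrix
    spot_ids: list[str]
    gene_ids: list[str]
    layer: str = "raw"

    def __post_init__(self) -> None:
        n, g = self.values.shape
        if n != len(self.spot_ids) or g != len(self.gene_ids):
            raise ValueError("values shape does not match identifier lengths")
        if len(set(self.spot_ids)) != n:
            raise ValueError("spot_ids are not unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids are not unique")
        if self.layer == "raw" and self.dense().size and self.dense().min() < 0:
            raise ValueError("raw counts contain negative entries")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)


@dataclass
class SpotCoordinates:
    """Planar spot positions, row-aligned with an :class:`ExpressionMatrix`."""

    positions: np.ndarray
    spot_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an n × 2 matrix")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite entries")
        if self.spot_ids and len(self.spot_ids) != self.positions.shape[0]:
            raise ValueError("spot_ids length does not match positions")


def _align(expr: ExpressionMatrix, coords: SpotCoordinates) -> tuple[ExpressionMatrix, SpotCoordinates]:
    """Reorder ``coords`` rows to the spot order of ``expr``."""
    pos_index = {s: i for i, s in enumerate(coords.spot_ids)}
    missing = [s for s in expr.spot_ids if s not in pos_index]
    extra = [s for s in coords.spot_ids if s not in set(expr.spot_ids)]
    if missing or extra:
        raise AlignmentError(
            "spot-ID mismatch between counts and coordinates; "
            f"missing coordinates for {missing[:5]}, "
            f"coordinates without counts for {extra[:5]}"
        )
    order = [pos_index[s] for s in expr.spot_ids]
    return expr, SpotCoordinates(coords.positions[order], list(expr.spot_ids))


def _load_csv(path: str) -> tuple[ExpressionMatrix, SpotCoordinates]:
    counts = pd.read_csv(os.path.join(path, "counts.csv"), index_col=0)
    coord_path = os.path.join(path, "coords.csv")
    if not os.path.exists(coord_path):
        raise FileNotFoundError("no spatial coordinates")
    cdf = pd.read_csv(coord_path)
    values = counts.to_numpy()
    if np.allclose(values, np.round(values)):
        values = values.astype(np.int64)
    expr = ExpressionMatrix(values, [str(s) for s in counts.index], [str(g) for g in counts.columns])
    coords = SpotCoordinates(cdf[["x", "y"]].to_numpy(float), [str(s) for s in cdf["spot_id"]])
    return _align(expr, coords)


def _find(path: str, names: list[str]) -> str:
    for name in names:
        p = os.path.join(path, name)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(f"none of {names} found in {path}")


def _load_mtx_dir(path: str) -> tuple[ExpressionMatrix, SpotCoordinates]:
    from scipy.io import mmread

    mat = sp.csr_matrix(mmread(_find(path, ["matrix.mtx", "matrix.mtx.gz"])))
    barcodes = pd.read_csv(_find(path, ["barcodes.tsv", "barcodes.tsv.gz"]), header=None, sep="\t")[0]
    genes = pd.read_csv(_find(path, ["features.tsv", "genes.tsv"]), header=None, sep="\t")[0]
    # genes × spots on disk (CellRanger convention) -> spots × genes in memory
    if mat.shape == (len(genes), len(barcodes)):
        mat = mat.T.tocsr()
    elif mat.shape != (len(barcodes), len(genes)):
        raise ValueError("matrix dimensions match neither barcodes × genes nor its transpose")
    try:
        pos_path = _find(path, ["positions.csv", "positions.tsv"])
    except FileNotFoundError as e:
        raise FileNotFoundError("no spatial coordinates") from e
    cdf = pd.read_csv(pos_path, sep="\t" if pos_path.endswith(".tsv") else ",")
    if mat.data.size and np.allclose(mat.data, np.round(mat.data)):
        mat = mat.astype(np.int64)
    expr = ExpressionMatrix(mat, [str(b) for b in barcodes], [str(g) for g in genes])
    coords = SpotCoordinates(cdf[["x", "y"]].to_numpy(float), [str(s) for s in cdf["spot_id"]])
    return _align(expr, coords)


def _load_h5(path: str) -> tuple[ExpressionMatrix, SpotCoordinates]:
    import anndata as ad

    adata = ad.read_h5ad(path)
    if "spatial" not in adata.obsm:
        raise KeyError("no spatial coordinates")
    x = adata.X
    if sp.issparse(x):
        x = sp.csr_matrix(x)
        if x.data.size and np.allclose(x.data, np.round(x.data)):
            x = x.astype(np.int64)
    else:
        x = np.asarray(x)
        if x.size and np.allclose(x, np.round(x)):
            x = x.astype(np.int64)
    expr = ExpressionMatrix(x, [str(s) for s in adata.obs_names], [str(g) for g in adata.var_names])
    coords = SpotCoordinates(np.asarray(adata.obsm["spatial"], float)[:, :2], list(expr.spot_ids))
    return expr, coords


_LOADERS = {"csv": _load_csv, "mtx_dir": _load_mtx_dir, "h5_container": _load_h5}


def load_dataset(path: str, format: str) -> tuple[ExpressionMatrix, SpotCoordinates]:
    """Load counts and coordinates from ``path`` in the given layout.

    Returns an (:class:`ExpressionMatrix`, :class:`SpotCoordinates`) pair with
    identical spot ordering. Raw integer counts are preserved as integers.
    """
    if format not in _LOADERS:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(_LOADERS)}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return _LOADERS[format](path)
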