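"""Expression preprocessing: library-size normalization, HVG selection, PCA.

The fixed pipeline is normalize → log1p → highly-variable-gene selection →
PCA; the top principal-component scores are the auto-encoder's input
features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import ExpressionMatrix, SpotCoordinates


@dataclass
class PCMatrix:
    """Spot × D principal-component scores.

    Columns are ordered by decreasing explained variance. ``mean`` (and
    ``scale`` when unit scaling was requested) record the gene-wise
    centering applied before the SVD.
    """

    scores: np.ndarray
    explained_variance: np.ndarray
    spot_ids: list[str] = field(default_factory=list)
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    @property
    def n_spots(self) -> int:
        return self.scores.shape[0]

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]


def normalize_log(raw: ExpressionMatrix, target_sum: float | None = None) -> ExpressionMatrix:
    """Scale each spot to a common library size, then apply log1p.

    ``target_sum`` defaults to the median library size of non-empty spots.
    Spots with zero total count carry no information and are dropped with a
    warning.
    """
    if raw.layer != "raw":
        raise ValueError("normalize_log expects raw counts")
    x = raw.dense().astype(float)
    lib = x.sum(axis=1)
    keep = lib > 0
    if not np.all(keep):
        dropped = [raw.spot_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping {len(dropped)} zero-count spot(s): {dropped[:5]}")
        x, lib = x[keep], lib[keep]
    if x.shape[0] == 0:
        raise ValueError("all spots have zero total count")
    if target_sum is None:
        target_sum = float(np.median(lib))
    x = np.log1p(x * (target_sum / lib)[:, None])
    return ExpressionMatrix(
        x,
        [s for s, k in zip(raw.spot_ids, keep) if k],
        list(raw.gene_ids),
        layer="normalized",
    )


def select_hvg(norm: ExpressionMatrix, n_top: int = 3000, flavor: str = "seurat") -> ExpressionMatrix:
    """Keep the ``n_top`` most variable genes of a normalized matrix.

    ``flavor="seurat"`` ranks genes by mean-binned normalized dispersion (the
    scanpy default); ``flavor="variance"`` ranks by plain variance, which is
    easier to reason about in tests. Gene order of the input is preserved
    among the survivors.
    """
    if norm.layer != "normalized":
        raise ValueError("select_hvg expects normalized data")
    if norm.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top >= norm.n_genes:
        return norm
    x = norm.dense()
    if flavor == "variance":
        var = x.var(axis=0, ddof=1)
        # stable tie-break on index keeps the selection deterministic
        order = np.lexsort((np.arange(len(var)), -var))
        keep_idx = np.sort(order[:n_top])
    elif flavor == "seurat":
        import anndata as ad
        import scanpy as sc

        adata = ad.AnnData(X=x.copy())
        adata.var_names = [str(g) for g in norm.gene_ids]
        sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
        keep_idx = np.flatnonzero(adata.var["highly_variable"].to_numpy())
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    return ExpressionMatrix(
        x[:, keep_idx],
        list(norm.spot_ids),
        [norm.gene_ids[i] for i in keep_idx],
        layer="normalized",
    )


def compute_pcs(
    hvg: ExpressionMatrix,
    n_pcs: int = 50,
    scale: bool = False,
    seed: int = 0,
) -> PCMatrix:
    """Project a normalized matrix onto its top principal components.

    Genes are centered (and optionally scaled to unit variance) before the
    SVD. The randomized solver, if selected by the backend, is seeded so the
    result is reproducible.
    """
    from sklearn.decomposition import PCA

    if hvg.layer != "normalized":
        raise ValueError("compute_pcs expects normalized data")
    x = hvg.dense().astype(float)
    if n_pcs > min(x.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(n_spots, n_genes)={min(x.shape)}")
    mu = x.mean(axis=0)
    sd = None
    if scale:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    pca = PCA(n_components=n_pcs, random_state=seed)
    scores = pca.fit_transform(x)
    return PCMatrix(
        scores=scores,
        explained_variance=pca.explained_variance_,
        spot_ids=list(hvg.spot_ids),
        mean=mu,
        scale=sd,
    )


def preprocess(
    raw: ExpressionMatrix,
    coords: SpotCoordinates,
    n_top_genes: int = 3000,
    n_pcs: int = 50,
    hvg_flavor: str = "seurat",
    scale: bool = False,
    seed: int = 0,
) -> tuple[PCMatrix, SpotCoordinates]:
    """Full pipeline from raw counts to PC scores, keeping coordinates aligned."""
    norm = normalize_log(raw)
    if len(norm.spot_ids) != len(raw.spot_ids):  # zero-count spots were dropped
        kept = set(norm.spot_ids)
        mask = np.array([s in kept for s in coords.spot_ids or raw.spot_ids])
        coords = SpotCoordinates(coords.positions[mask], list(norm.spot_ids))
    hvg = select_hvg(norm, n_top=n_top_genes, flavor=hvg_flavor)
    n_pcs = min(n_pcs, hvg.n_spots, hvg.n_genes)
    return compute_pcs(hvg, n_pcs=n_pcs, scale=scale, seed=seed), coords
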