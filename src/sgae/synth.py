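"""Synthetic spatial transcriptomic data with known layered domains.

The generator emulates the structure of laminar tissues (cortical layers,
olfactory-bulb laminae): spots on a planar grid, domains as contiguous
horizontal bands (or concentric rings), each domain carrying a private set
of marker genes whose mean count is elevated on the log scale, counts drawn
from a Poisson or negative-binomial model. Everything is reproducible from
the config seed, and the writers emit the same on-disk layouts the readers
accept, so end-to-end tests round-trip through real I/O.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import DomainLabels
from .io import ExpressionMatrix, SpotCoordinates


@dataclass
class SynthConfig:
    """Generator settings; defaults give a 3000-spot, 5-band tissue."""

    n_spots: int = 3000
    n_domains: int = 5
    n_genes: int = 200
    n_marker_genes: int = 10
    effect: float = 1.5       # log-scale mean shift of markers inside their domain
    baseline: float = 5.0     # background mean count
    noise: str = "poisson"    # or "nb"
    theta: float = 10.0       # NB overdispersion (var = mu + mu²/theta)
    dropout: float = 0.0
    geometry: str = "bands"   # or "rings"
    grid: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 2:
            raise ValueError("need at least 2 domains")
        if self.n_marker_genes < 1:
            raise ValueError("need at least 1 marker gene per domain")
        if self.effect < 0:
            raise ValueError("effect size must be >= 0")
        if self.n_domains * self.n_marker_genes > self.n_genes:
            raise ValueError("marker sets exceed the number of genes")
        if self.noise not in ("poisson", "nb"):
            raise ValueError("noise must be 'poisson' or 'nb'")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


def _grid_positions(n_spots: int) -> tuple[np.ndarray, int, int]:
    ny = int(round(np.sqrt(n_spots)))
    nx = int(np.ceil(n_spots / ny))
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny))
    pos = np.column_stack([xs.ravel(), ys.ravel()])[:n_spots].astype(float)
    return pos, nx, ny


def marker_genes(cfg: SynthConfig) -> dict[int, list[str]]:
    """Marker gene ids per domain (block layout: domain d owns genes d·M..d·M+M)."""
    M = cfg.n_marker_genes
    return {
        d: [f"gene_{j:04d}" for j in range(d * M, (d + 1) * M)]
        for d in range(cfg.n_domains)
    }


def generate_layered_dataset(
    cfg: SynthConfig,
) -> tuple[ExpressionMatrix, SpotCoordinates, DomainLabels]:
    """Draw a synthetic dataset; returns raw counts, coordinates, true domains."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.grid:
        pos, _, ny = _grid_positions(cfg.n_spots)
        if cfg.geometry == "bands":
            if cfg.n_domains > ny:
                raise ValueError(f"{cfg.n_domains} bands do not fit a grid of height {ny}")
            domain = np.minimum((pos[:, 1] * cfg.n_domains / ny).astype(int), cfg.n_domains - 1)
        elif cfg.geometry == "rings":
            center = pos.mean(axis=0)
            r = np.linalg.norm(pos - center, axis=1)
            edges = np.quantile(r, np.linspace(0, 1, cfg.n_domains + 1)[1:-1])
            domain = np.searchsorted(edges, r, side="right")
        else:
            raise ValueError(f"unknown geometry {cfg.geometry!r}")
    else:
        pos = rng.uniform(0, np.sqrt(cfg.n_spots), size=(cfg.n_spots, 2))
        ny = None
        domain = np.minimum(
            (pos[:, 1] * cfg.n_domains / np.sqrt(cfg.n_spots)).astype(int),
            cfg.n_domains - 1,
        )

    mean = np.full((cfg.n_spots, cfg.n_genes), float(cfg.baseline))
    M = cfg.n_marker_genes
    for d in range(cfg.n_domains):
        rows = domain == d
        mean[np.ix_(rows, np.arange(d * M, (d + 1) * M))] = cfg.baseline * np.exp(cfg.effect)

    if cfg.noise == "poisson":
        counts = rng.poisson(mean)
    else:
        p = cfg.theta / (cfg.theta + mean)
        counts = rng.negative_binomial(cfg.theta, p)
    if cfg.dropout > 0:
        counts = counts * (rng.random(counts.shape) >= cfg.dropout)

    spot_ids = [f"spot_{i:05d}" for i in range(cfg.n_spots)]
    gene_ids = [f"gene_{j:04d}" for j in range(cfg.n_genes)]
    expr = ExpressionMatrix(counts.astype(np.int64), spot_ids, gene_ids, layer="raw")
    coords = SpotCoordinates(pos, spot_ids)
    return expr, coords, DomainLabels(domain, K=cfg.n_domains)


def score_ari(labels: DomainLabels, truth: DomainLabels) -> float:
    """Adjusted Rand index between two partitions (chance-corrected, in [−1, 1])."""
    from sklearn.metrics import adjusted_rand_score

    if labels.n_spots != truth.n_spots:
        raise ValueError("partitions have different lengths")
    return float(adjusted_rand_score(truth.labels, labels.labels))


def write_dataset(
    expr: ExpressionMatrix,
    coords: SpotCoordinates,
    outdir: str,
    format: str = "csv",
) -> None:
    """Write a dataset in a layout :func:`sgae.io.load_dataset` can read back."""
    os.makedirs(outdir, exist_ok=True)
    cdf = pd.DataFrame(
        {"spot_id": expr.spot_ids, "x": coords.positions[:, 0], "y": coords.positions[:, 1]}
    )
    if format == "csv":
        pd.DataFrame(expr.dense(), index=expr.spot_ids, columns=expr.gene_ids).to_csv(
            os.path.join(outdir, "counts.csv")
        )
        cdf.to_csv(os.path.join(outdir, "coords.csv"), index=False)
    elif format == "mtx_dir":
        import scipy.sparse as sp
        from scipy.io import mmwrite

        mmwrite(os.path.join(outdir, "matrix.mtx"), sp.csr_matrix(expr.dense().T))
        pd.Series(expr.spot_ids).to_csv(
            os.path.join(outdir, "barcodes.tsv"), index=False, header=False
        )
        pd.Series(expr.gene_ids).to_csv(
            os.path.join(outdir, "genes.tsv"), index=False, header=False
        )
        cdf.to_csv(os.path.join(outdir, "positions.csv"), index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
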