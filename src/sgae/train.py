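"""Mini-batch SGD training loop and deterministic embedding extraction.

Spots are split into ⌈N/n⌉ disjoint batches per epoch (reshuffled each epoch
from the run seed). Each batch builds its own adjacency pair, so peak memory
scales with the batch size n, never with the dataset size N — the property
that makes the method usable on datasets with 10⁵⁺ spots. Inference batching
is sequential and shuffle-free so embeddings are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .graph import make_batch_graph
from .model import EmbeddingMatrix, ModelParams, encode, init_params, loss_and_grads
from .preprocess import PCMatrix
from .io import SpotCoordinates

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Hyperparameters of the training loop.

    Defaults follow the published method: batches of 2000 spots, 100 epochs
    of plain SGD at learning rate 0.2 dropping to 0.1 for the last 20
    epochs, and τ = 0.07 for both adjacency views. ``normalization``
    defaults to symmetric degree normalization of the adjacencies — the
    stability preset; ``"none"`` gives the literal un-normalized update.
    """

    batch_size: int = 2000
    epochs: int = 100
    lr_initial: float = 0.2
    lr_final: float = 0.1
    lr_drop_epoch: int | None = None  # first epoch at lr_final; default epochs-19
    tau_e: float = 0.07
    tau_p: float = 0.07
    seed: int = 0
    precision: str = "single"
    variant: str = "full"
    normalization: str = "sym_degree"
    output_activation: str = "elu"
    momentum: float = 0.0
    shuffle: bool = True
    reshuffle_each_epoch: bool = True

    def __post_init__(self) -> None:
        if self.lr_drop_epoch is None:
            self.lr_drop_epoch = max(1, self.epochs - 19)
        if not 0 < self.lr_final <= self.lr_initial:
            raise ValueError("need 0 < lr_final <= lr_initial")
        if not 1 <= self.lr_drop_epoch <= self.epochs:
            raise ValueError("lr_drop_epoch out of range")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")


@dataclass
class TrainHistory:
    """Per-epoch record of the optimization."""

    epoch_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    batch_count: list[int] = field(default_factory=list)


def make_batches(N: int, n: int, seed: int = 0, shuffle: bool = True) -> list[np.ndarray]:
    """Split ``N`` indices into ⌈N/n⌉ disjoint batches.

    The last batch may be smaller; a trailing batch of a single spot cannot
    support a graph and is merged into the previous batch.
    """
    if N < 2 or n < 2:
        raise ValueError("need N >= 2 and n >= 2")
    idx = np.arange(N)
    if shuffle:
        idx = np.random.default_rng(seed).permutation(N)
    batches = [idx[i : i + n] for i in range(0, N, n)]
    if len(batches) > 1 and len(batches[-1]) == 1:
        tail = batches.pop()
        batches[-1] = np.concatenate([batches[-1], tail])
    return batches


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Step learning-rate schedule; ``epoch`` is 1-based."""
    if not 1 <= epoch <= cfg.epochs:
        raise ValueError("epoch out of range")
    return cfg.lr_final if epoch >= cfg.lr_drop_epoch else cfg.lr_initial


def fit(
    pcs: PCMatrix | np.ndarray,
    coords: SpotCoordinates | np.ndarray,
    cfg: TrainConfig,
) -> tuple[ModelParams, TrainHistory]:
    """Train the auto-encoder by mini-batch SGD.

    Fully reproducible from ``cfg.seed``: parameter initialization and every
    epoch's batch composition derive from it. Raises on a non-finite loss,
    naming the epoch and batch.
    """
    X = pcs.scores if isinstance(pcs, PCMatrix) else np.asarray(pcs, float)
    P = coords.positions if isinstance(coords, SpotCoordinates) else np.asarray(coords, float)
    if X.shape[0] != P.shape[0]:
        raise ValueError("pcs and coords are not row-aligned")
    N, D = X.shape
    params = init_params(D, variant=cfg.variant, seed=cfg.seed)
    vel = {k: None for k in ("B1", "B2")}
    history = TrainHistory()
    for epoch in range(1, cfg.epochs + 1):
        lr = lr_at(epoch, cfg)
        batch_seed = cfg.seed + epoch if cfg.reshuffle_each_epoch else cfg.seed + 1
        batches = make_batches(N, cfg.batch_size, seed=batch_seed, shuffle=cfg.shuffle)
        losses = []
        for b, idx in enumerate(batches):
            graph = make_batch_graph(
                X[idx],
                P[idx],
                tau_e=cfg.tau_e,
                tau_p=cfg.tau_p,
                precision=cfg.precision,
                member_indices=idx,
                normalize=cfg.normalization,
            )
            loss, g1, g2 = loss_and_grads(X[idx], graph, params, cfg.output_activation)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, batch {b}")
            for name, g in (("B1", g1), ("B2", g2)):
                if g is None:
                    continue
                if cfg.momentum > 0:
                    v = vel[name]
                    v = cfg.momentum * v + g if v is not None else g
                    vel[name] = v
                    g = v
                setattr(params, name, getattr(params, name) - lr * g)
            losses.append(loss)
        history.epoch_loss.append(float(np.mean(losses)))
        history.learning_rate.append(lr)
        history.batch_count.append(len(losses))
        logger.info("epoch %d/%d lr=%.3g loss=%.6g", epoch, cfg.epochs, lr, history.epoch_loss[-1])
    return params, history


def extract_embeddings(
    pcs: PCMatrix | np.ndarray,
    coords: SpotCoordinates | np.ndarray,
    params: ModelParams,
    cfg: TrainConfig,
) -> EmbeddingMatrix:
    """Encode every spot with trained parameters.

    Spots are processed in sequential (unshuffled) batches of the training
    batch size, each with its own adjacency pair, and rows are reassembled
    in dataset order. There is no randomness at inference, so repeated calls
    are bit-identical. Embeddings do depend on batch composition — inherent
    to per-batch graphs — which the fixed sequential split keeps stable.
    """
    X = pcs.scores if isinstance(pcs, PCMatrix) else np.asarray(pcs, float)
    P = coords.positions if isinstance(coords, SpotCoordinates) else np.asarray(coords, float)
    spot_ids = pcs.spot_ids if isinstance(pcs, PCMatrix) else None
    N = X.shape[0]
    out = np.empty((N, params.D))
    for idx in make_batches(N, cfg.batch_size, shuffle=False):
        graph = make_batch_graph(
            X[idx],
            P[idx],
            tau_e=cfg.tau_e,
            tau_p=cfg.tau_p,
            precision=cfg.precision,
            member_indices=idx,
            normalize=cfg.normalization,
        )
        out[idx] = encode(X[idx], graph, params)
    return EmbeddingMatrix(out, spot_ids)


def single_batch_config(cfg: TrainConfig, N: int) -> TrainConfig:
    """A copy of ``cfg`` whose batch size covers all ``N`` spots (full-batch)."""
    return replace(cfg, batch_size=max(N, 2))
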