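"""Symmetric graph-convolutional auto-encoder.

Encoder (Laplacian smoothing), for one mini-batch with feature matrix X
(n × D) and adjacencies W_e, W_p::

    H1 = ELU(W_e · X  · B1)      # aggregate over expression similarity
    H2 = ELU(W_p · H1 · B2)      # aggregate over spatial proximity

Decoder (Laplacian sharpening) mirrors the encoder with Ŵ = 3·I − W and the
transposed projections — it introduces no parameters of its own::

    Ĥ1 = ELU((3I − W_p) · H2 · B2ᵀ)
    X̂  = δ_out((3I − W_e) · Ĥ1 · B1ᵀ)

H2 is the latent embedding used for spatial-domain identification. The only
trainable parameters are the two D × D projections B1 and B2 (2·D² scalars);
the ablation variants keep a single view and a single D² projection.
Gradients of the mean-squared reconstruction error with respect to B1 and B2
are derived by hand below and checked against finite differences in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import MiniBatchGraph, sharpen_adjacency

VARIANTS = ("full", "exp_only", "spa_only")


@dataclass
class ModelParams:
    """Trainable projections of the auto-encoder."""

    B1: np.ndarray | None
    B2: np.ndarray | None
    D: int
    variant: str = "full"

    def n_parameters(self) -> int:
        return sum(b.size for b in (self.B1, self.B2) if b is not None)

    def copy(self) -> "ModelParams":
        return ModelParams(
            None if self.B1 is None else self.B1.copy(),
            None if self.B2 is None else self.B2.copy(),
            self.D,
            self.variant,
        )

    def save(self, path: str) -> None:
        np.savez(
            path,
            B1=np.empty(0) if self.B1 is None else self.B1,
            B2=np.empty(0) if self.B2 is None else self.B2,
            D=self.D,
            variant=self.variant,
        )

    @classmethod
    def load(cls, path: str) -> "ModelParams":
        z = np.load(path, allow_pickle=False)
        b1, b2 = z["B1"], z["B2"]
        return cls(
            b1 if b1.size else None,
            b2 if b2.size else None,
            int(z["D"]),
            str(z["variant"]),
        )


@dataclass
class EmbeddingMatrix:
    """Spot × D latent representations (the encoder output H2)."""

    values: np.ndarray
    spot_ids: list[str] | None = None


def init_params(D: int, variant: str = "full", seed: int = 0) -> ModelParams:
    """Fan-in-scaled uniform initialization, reproducible from ``seed``."""
    if D < 1:
        raise ValueError("D must be >= 1")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(seed)
    bound = np.sqrt(1.0 / D)

    def draw():
        return rng.uniform(-bound, bound, size=(D, D))

    b1 = draw() if variant in ("full", "exp_only") else None
    b2 = draw() if variant in ("full", "spa_only") else None
    return ModelParams(b1, b2, D, variant)


def elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0)))


def _elu_grad(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, 1.0, np.exp(np.minimum(z, 0)))


def _act(z, kind):
    return elu(z) if kind == "elu" else z


def _act_grad(z, kind):
    return _elu_grad(z) if kind == "elu" else np.ones_like(z)


def _check(X, graph: MiniBatchGraph, params: ModelParams):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != graph.n:
        raise ValueError("X rows do not match graph membership")
    if X.shape[1] != params.D:
        raise ValueError(f"feature dimension {X.shape[1]} != params.D {params.D}")
    return X


def encode(X: np.ndarray, graph: MiniBatchGraph, params: ModelParams) -> np.ndarray:
    """Latent embedding H2 of one batch."""
    X = _check(X, graph, params)
    if params.variant == "full":
        h1 = elu(graph.W_e @ X @ params.B1)
        return elu(graph.W_p @ h1 @ params.B2)
    if params.variant == "exp_only":
        return elu(graph.W_e @ X @ params.B1)
    return elu(graph.W_p @ X @ params.B2)


def decode(
    H2: np.ndarray,
    graph: MiniBatchGraph,
    params: ModelParams,
    output_activation: str = "elu",
) -> np.ndarray:
    """Reconstruct the input features from a latent embedding."""
    H2 = _check(H2, graph, params)
    if params.variant == "full":
        hh1 = elu(sharpen_adjacency(graph.W_p) @ H2 @ params.B2.T)
        return _act(sharpen_adjacency(graph.W_e) @ hh1 @ params.B1.T, output_activation)
    if params.variant == "exp_only":
        return _act(sharpen_adjacency(graph.W_e) @ H2 @ params.B1.T, output_activation)
    return _act(sharpen_adjacency(graph.W_p) @ H2 @ params.B2.T, output_activation)


def reconstruction_loss(X: np.ndarray, Xhat: np.ndarray, reduction: str = "frobenius") -> float:
    """Reconstruction error ‖X − X̂‖: Frobenius norm, or MSE for optimizer scaling."""
    X, Xhat = np.asarray(X, float), np.asarray(Xhat, float)
    if X.shape != Xhat.shape:
        raise ValueError("shape mismatch")
    if reduction == "frobenius":
        return float(np.linalg.norm(X - Xhat))
    if reduction == "mse":
        return float(np.mean((X - Xhat) ** 2))
    raise ValueError(f"unknown reduction {reduction!r}")


def loss_and_grads(
    X: np.ndarray,
    graph: MiniBatchGraph,
    params: ModelParams,
    output_activation: str = "elu",
) -> tuple[float, np.ndarray | None, np.ndarray | None]:
    """MSE reconstruction loss and its gradients w.r.t. B1 and B2.

    One forward pass caches the pre-activations; the backward pass applies
    the chain rule layer by layer, exploiting the symmetry of the adjacency
    matrices (Wᵀ = W, and (3I−W)ᵀ = 3I−W).
    """
    X = _check(X, graph, params)
    n, D = X.shape
    B1, B2 = params.B1, params.B2

    if params.variant == "full":
        We, Wp = graph.W_e, graph.W_p
        Se, Sp = sharpen_adjacency(We), sharpen_adjacency(Wp)
        WeX = We @ X
        Z1 = WeX @ B1
        H1 = elu(Z1)
        WpH1 = Wp @ H1
        Z2 = WpH1 @ B2
        H2 = elu(Z2)
        SpH2 = Sp @ H2
        Z3 = SpH2 @ B2.T
        Hh1 = elu(Z3)
        SeHh1 = Se @ Hh1
        Z4 = SeHh1 @ B1.T
        Xhat = _act(Z4, output_activation)

        loss = float(np.mean((X - Xhat) ** 2))
        dZ4 = (2.0 / (n * D)) * (Xhat - X) * _act_grad(Z4, output_activation)
        gB1 = dZ4.T @ SeHh1          # from X̂ = δ(Se·Ĥ1·B1ᵀ)
        dHh1 = (Se @ dZ4) @ B1
        dZ3 = dHh1 * _elu_grad(Z3)
        gB2 = dZ3.T @ SpH2           # from Ĥ1 = δ(Sp·H2·B2ᵀ)
        dH2 = (Sp @ dZ3) @ B2
        dZ2 = dH2 * _elu_grad(Z2)
        gB2 = gB2 + WpH1.T @ dZ2     # from H2 = δ(Wp·H1·B2)
        dH1 = (Wp @ dZ2) @ B2.T
        dZ1 = dH1 * _elu_grad(Z1)
        gB1 = gB1 + WeX.T @ dZ1      # from H1 = δ(We·X·B1)
        return loss, gB1, gB2

    # single-view ablations: one smoothing layer, one sharpening layer
    W = graph.W_e if params.variant == "exp_only" else graph.W_p
    B = B1 if params.variant == "exp_only" else B2
    S = sharpen_adjacency(W)
    WX = W @ X
    Z1 = WX @ B
    H = elu(Z1)
    SH = S @ H
    Z2 = SH @ B.T
    Xhat = _act(Z2, output_activation)
    loss = float(np.mean((X - Xhat) ** 2))
    dZ2 = (2.0 / (n * D)) * (Xhat - X) * _act_grad(Z2, output_activation)
    gB = dZ2.T @ SH
    dH = (S @ dZ2) @ B
    dZ1 = dH * _elu_grad(Z1)
    gB = gB + WX.T @ dZ1
    if params.variant == "exp_only":
        return loss, gB, None
    return loss, None, gB
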