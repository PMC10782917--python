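"""Per-mini-batch Gaussian-kernel adjacency matrices with adaptive bandwidth.

For each mini-batch two symmetric adjacency matrices are built: ``W_e`` from
Euclidean distances between principal-component vectors (expression
similarity) and ``W_p`` from distances between tissue coordinates (spatial
proximity). Entries are ``exp(-d²/(2l²))``. The bandwidth ``l`` is not a
free parameter: it is solved from ``-d_tau²/(2l²) = m`` where ``d_tau`` is
the τ-quantile of the batch's off-diagonal distances and ``m`` is the most
negative integer exponent at which ``exp`` still evaluates to exactly zero
in the working floating-point precision. Entries at or beyond the quantile
distance therefore underflow to exact zeros, so the fraction of nonzero
off-diagonal entries equals τ in every batch regardless of its composition
— every batch has the same average neighbor count.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

_DTYPES = {"single": np.float32, "double": np.float64}

#: batches up to this size keep dense ndarray adjacencies (test-friendly);
#: larger batches use CSR with underflowed zeros absent
_DENSE_MAX = 64


class DegenerateBatchError(ValueError):
    """All relevant pairwise distances are zero; no bandwidth exists."""


@dataclass
class MiniBatchGraph:
    """Adjacency pair and bandwidths for one mini-batch of spots."""

    member_indices: np.ndarray
    W_e: np.ndarray | sp.spmatrix
    W_p: np.ndarray | sp.spmatrix
    l_e: float
    l_p: float
    tau_e: float
    tau_p: float
    m: int

    @property
    def n(self) -> int:
        return len(self.member_indices)


def pairwise_distance(points: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix of an n × d point set."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("batch too small")
    if not np.all(np.isfinite(points)):
        raise ValueError("points contain non-finite entries")
    d = cdist(points, points)
    np.fill_diagonal(d, 0.0)
    return d


@lru_cache(maxsize=None)
def underflow_constant(precision: str = "single") -> int:
    """Largest (least negative) integer m with ``exp(m) == 0`` in ``precision``.

    Probed at runtime rather than hard-coded so the exact-sparsity property
    holds on any IEEE-compliant platform (−104 for binary32, −746 for
    binary64 on conventional hardware).
    """
    dtype = _DTYPES[precision]
    m = -1
    while np.exp(dtype(2 * m)) > 0:
        m *= 2
    lo, hi = 2 * m, m  # exp(lo) == 0 < exp(hi)... invariant: exp(hi) > 0
    while np.exp(dtype(lo)) > 0:
        lo *= 2
    while hi - lo > 1:
        mid = (hi + lo) // 2
        if np.exp(dtype(mid)) > 0:
            hi = mid
        else:
            lo = mid
    return lo


def quantile_threshold(D: np.ndarray, tau: float, include_diagonal: bool = False) -> float:
    """τ-quantile (linear interpolation) of the pairwise-distance population.

    By default the population is the off-diagonal entries only: including
    the diagonal's n structural zeros would bias the quantile low at small
    batch sizes and break the exact τ-sparsity property.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    D = np.asarray(D, dtype=float)
    if include_diagonal:
        vals = D.ravel()
    else:
        n = D.shape[0]
        vals = D[~np.eye(n, dtype=bool)]
    if np.all(vals == 0):
        raise DegenerateBatchError("degenerate batch: all pairwise distances are zero")
    d_tau = float(np.quantile(vals, tau))
    if d_tau == 0:
        raise DegenerateBatchError("degenerate batch: quantile distance is zero")
    return d_tau


def solve_bandwidth(d_tau: float, m: int) -> float:
    """Bandwidth l solving ``-d_tau²/(2l²) = m``, i.e. ``l = d_tau/sqrt(-2m)``."""
    if d_tau <= 0:
        raise DegenerateBatchError("degenerate batch: quantile distance is zero")
    if m >= 0:
        raise ValueError("underflow constant must be negative")
    return float(d_tau / np.sqrt(-2.0 * m))


def build_adjacency(
    D: np.ndarray,
    l: float,
    precision: str = "single",
    d_tau: float | None = None,
) -> np.ndarray | sp.csr_matrix:
    """Gaussian-kernel adjacency ``W[u,v] = exp(-D[u,v]²/(2l²))``.

    Evaluated in the requested precision so that entries whose exponent is at
    or below the underflow constant are exactly zero. When ``d_tau`` is given
    (the bandwidth came from :func:`solve_bandwidth`) two boundary guards are
    applied so the support of ``W`` is exactly ``{D < d_tau}``: the exponent
    at ``D == d_tau`` is computed as exactly ``m`` despite rounding, and
    kernel values inside the threshold that underflow anyway (``exp(x)`` is
    zero for all x below ln(minsubnormal/2), not only integer exponents) are
    rounded up to the smallest subnormal. Large batches are returned as CSR
    with zeros absent; batches of ≤ 64 spots stay dense.
    """
    if l <= 0:
        raise ValueError("bandwidth must be positive")
    dtype = _DTYPES[precision]
    D = np.asarray(D, dtype=float)
    if d_tau is not None:
        m = underflow_constant(precision)
        # (D/d_tau)² is exactly 1.0 at the threshold, so the exponent is exactly m
        expo = (m * (D / d_tau) ** 2).astype(dtype)
    else:
        expo = (-(D**2) / (2.0 * l * l)).astype(dtype)
    W = np.exp(expo)
    if d_tau is not None:
        inside = D < d_tau
        tiny = np.nextafter(dtype(0), dtype(1))
        W[inside & (W == 0)] = tiny
        W[~inside] = 0.0
    np.fill_diagonal(W, 1.0)
    W = W.astype(float)
    if W.shape[0] > _DENSE_MAX:
        return sp.csr_matrix(W)
    return W


def make_batch_graph(
    pcs: np.ndarray,
    coords: np.ndarray,
    tau_e: float = 0.07,
    tau_p: float = 0.07,
    precision: str = "single",
    member_indices: np.ndarray | None = None,
    normalize: str = "none",
) -> MiniBatchGraph:
    """Build the (W_e, W_p) pair for one batch of spots.

    ``pcs`` and ``coords`` must be row-aligned. ``normalize`` optionally
    applies symmetric degree normalization to both matrices (see
    :func:`normalize_adjacency`); the raw construction follows the literal
    model equations with ``none``.
    """
    pcs = np.asarray(pcs, float)
    coords = np.asarray(coords, float)
    if pcs.shape[0] != coords.shape[0]:
        raise ValueError("pcs and coords are not row-aligned")
    if pcs.shape[0] < 2:
        raise ValueError("batch too small")
    m = underflow_constant(precision)
    ws, ls = [], []
    for pts, tau, view in ((pcs, tau_e, "expression"), (coords, tau_p, "spatial")):
        D = pairwise_distance(pts)
        try:
            d_tau = quantile_threshold(D, tau)
        except DegenerateBatchError as e:
            raise DegenerateBatchError(f"{view} view: {e}") from None
        l = solve_bandwidth(d_tau, m)
        W = build_adjacency(D, l, precision=precision, d_tau=d_tau)
        ws.append(normalize_adjacency(W, mode=normalize))
        ls.append(l)
    if member_indices is None:
        member_indices = np.arange(pcs.shape[0])
    return MiniBatchGraph(
        member_indices=np.asarray(member_indices),
        W_e=ws[0],
        W_p=ws[1],
        l_e=ls[0],
        l_p=ls[1],
        tau_e=tau_e,
        tau_p=tau_p,
        m=m,
    )


def normalize_adjacency(W, mode: str = "none"):
    """Optionally apply symmetric degree normalization Deg^{-1/2} W Deg^{-1/2}."""
    if mode == "none":
        return W
    if mode != "sym_degree":
        raise ValueError(f"unknown normalization mode {mode!r}")
    if sp.issparse(W):
        deg = np.asarray(W.sum(axis=1)).ravel()
        dinv = sp.diags(1.0 / np.sqrt(deg))
        return (dinv @ W @ dinv).tocsr()
    deg = W.sum(axis=1)
    dinv = 1.0 / np.sqrt(deg)
    return W * dinv[:, None] * dinv[None, :]


def sharpen_adjacency(W):
    """Laplacian-sharpening counterpart of a smoothing adjacency: ``3·I − W``."""
    n = W.shape[0]
    if W.shape[1] != n:
        raise ValueError("W must be square")
    if sp.issparse(W):
        return (3.0 * sp.identity(n, format="csr") - W).tocsr()
    return 3.0 * np.eye(n) - np.asarray(W, float)


def offdiag_nonzero_fraction(W) -> float:
    """Fraction of strictly positive off-diagonal entries (τ-sparsity probe)."""
    n = W.shape[0]
    if sp.issparse(W):
        nnz = W.copy()
        nnz.setdiag(0)
        nnz.eliminate_zeros()
        count = (nnz.data > 0).sum()
    else:
        off = ~np.eye(n, dtype=bool)
        count = int((np.asarray(W)[off] > 0).sum())
    return count / (n * (n - 1))
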