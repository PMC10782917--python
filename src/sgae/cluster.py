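"""Spatial-domain assignment from latent embeddings.

When the number of domains is known a Gaussian-mixture model is fitted to
the embeddings (model-based clustering in the mclust tradition, here a
full-covariance GMM with seeded multi-restart EM); without prior knowledge,
Louvain community detection on a k-nearest-neighbor graph of the embeddings
is used. Either result can then be spatially refined: a spot whose label is
shared by at most half of its spatial neighbors, while some other single
label is held by more than half, is relabeled to that majority label.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import numpy as np

from .io import SpotCoordinates
from .model import EmbeddingMatrix


@dataclass
class DomainLabels:
    """Per-spot integer domain assignments."""

    labels: np.ndarray
    K: int
    refined: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and not (0 <= self.labels.min() and self.labels.max() < self.K):
            raise ValueError("labels out of range [0, K)")

    @property
    def n_spots(self) -> int:
        return self.labels.shape[0]


def _embedding_values(E) -> np.ndarray:
    return E.values if isinstance(E, EmbeddingMatrix) else np.asarray(E, float)


def gmm_cluster(E, k: int, seed: int = 0, n_init: int = 5) -> DomainLabels:
    """Full-covariance Gaussian-mixture clustering with ``k`` components.

    EM is restarted ``n_init`` times from seeded initializations and the
    best-likelihood fit is kept; spots are hard-assigned by maximum
    posterior.
    """
    from sklearn.mixture import GaussianMixture

    x = _embedding_values(E)
    if not 2 <= k <= x.shape[0]:
        raise ValueError("need 2 <= k <= n_spots")
    try:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
            reg_covar=1e-6,
        )
        labels = gm.fit_predict(x)
    except Exception as e:  # pragma: no cover - backend failure surface
        raise RuntimeError(f"EM failed on all restarts: {e}") from e
    return DomainLabels(labels, K=k)


def louvain_cluster(
    E,
    resolution: float = 1.2,
    n_neighbors: int = 15,
    seed: int = 0,
) -> DomainLabels:
    """Louvain modularity clustering on a kNN graph of the embeddings.

    The number of communities is determined by the partition; it can be
    steered with ``resolution`` and with the neighbor count of the graph.
    """
    import igraph
    from sklearn.neighbors import NearestNeighbors

    x = _embedding_values(E)
    n = x.shape[0]
    if n_neighbors < 2:
        raise ValueError("n_neighbors must be >= 2")
    nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, n)).fit(x)
    _, nbr = nn.kneighbors(x)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(nbr) for j in row[1:]}
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(resolution=resolution)
    labels = np.asarray(part.membership)
    return DomainLabels(labels, K=int(labels.max()) + 1)


def refine_labels(
    labels: DomainLabels,
    coords: SpotCoordinates | np.ndarray,
    k_neighbors: int = 6,
    iterate: bool = False,
) -> DomainLabels:
    """Majority-vote spatial refinement of domain labels.

    For each spot the ``k_neighbors`` nearest spatial neighbors are polled
    (all votes taken from the pre-pass labels, one simultaneous update): if
    the spot's own label is held by at most half of them and some other
    single label by strictly more than half, the spot adopts that label.
    The default neighborhood of 6 matches the hexagonal lattice of Visium
    arrays. ``iterate=True`` repeats passes until a fixed point.
    """
    from sklearn.neighbors import NearestNeighbors

    pos = coords.positions if isinstance(coords, SpotCoordinates) else np.asarray(coords, float)
    n = pos.shape[0]
    if labels.n_spots != n:
        raise ValueError("labels and coords are not aligned")
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of spots")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(pos)
    _, nbr = nn.kneighbors(pos)
    nbr = nbr[:, 1:]  # drop self

    current = labels.labels.copy()
    for _ in range(n if iterate else 1):
        votes = current[nbr]
        new = current.copy()
        for i in range(n):
            counts = np.bincount(votes[i], minlength=labels.K)
            own = counts[current[i]]
            top = int(np.argmax(counts))
            if top != current[i] and own * 2 <= k_neighbors and counts[top] * 2 > k_neighbors:
                new[i] = top
        if np.array_equal(new, current):
            break
        current = new
        if not iterate:
            break
    else:  # pragma: no cover - safety valve
        warnings.warn("refinement did not converge within n_spots passes")
    return DomainLabels(current, K=labels.K, refined=True)
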