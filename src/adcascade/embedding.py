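"""ISOMAP embedding of a pairwise shape-distance matrix, with diagnostics.

ISOMAP proceeds in two steps: all-pairs shortest-path (geodesic)
distances on a symmetric k-nearest-neighbour graph, then classical
multidimensional scaling of the double-centered squared-distance kernel
B = -1/2 J D^2 J. Each retained eigenvector is one shape component.
Diagnostics cover embedding fidelity (Pearson correlation between the
embedded Euclidean distances and the input metric distances) and
per-component correlation with structure volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .errors import DegenerateStatisticError, DisconnectedGraphError
from .shape_metric import DistanceMatrix

log = logging.getLogger(__name__)


@dataclass
class ShapeEmbedding:
    """Per-subject coordinates on the leading components of the embedding.

    ``coordinates`` is (n_subjects, m) with columns ordered by
    nonincreasing eigenvalue; columns have zero mean. ``eigenvalues``
    keeps the raw (possibly negative) kernel eigenvalues for diagnostics;
    negative ones are clamped to zero when forming coordinates.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    subject_ids: list
    neighbors_k: int | None = None
    fidelity_r: float | None = None

    @property
    def n_components(self) -> int:
        return int(self.coordinates.shape[1])

    def component(self, index: int) -> np.ndarray:
        """1-based component accessor (component 1 = leading eigenvector)."""
        return self.coordinates[:, index - 1]


def _knn_graph(d: np.ndarray, k: int) -> csr_matrix:
    n = len(d)
    order = np.argsort(d, axis=1, kind="stable")
    rows, cols = [], []
    for i in range(n):
        neigh = [j for j in order[i] if j != i][:k]
        rows.extend([i] * len(neigh))
        cols.extend(neigh)
    w = d[rows, cols]
    g = csr_matrix((w, (rows, cols)), shape=(n, n))
    return g.maximum(g.T)  # symmetric union: edge if either end nominates it


def geodesic_distances(D: DistanceMatrix, k: int) -> DistanceMatrix:
    """All-pairs shortest-path distances on the symmetric k-NN graph of D.

    Raises :class:`DisconnectedGraphError` naming the component sizes when
    the graph is disconnected.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    g = _knn_graph(D.values, k)
    n_comp, labels = connected_components(g, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise DisconnectedGraphError(
            f"k-NN graph (k={k}) has {n_comp} components of sizes {sizes}; "
            "increase k"
        )
    geo = shortest_path(g, method="D", directed=False)
    return DistanceMatrix(geo, list(D.subject_ids))


def classical_scaling(D: DistanceMatrix, m: int) -> ShapeEmbedding:
    """Classical MDS: eigendecomposition of B = -1/2 J D^2 J.

    Coordinates are the top-``m`` eigenvectors scaled by the square root
    of their (nonnegative-clamped) eigenvalues; exact for any distance
    matrix realizable in m-dimensional Euclidean space. Eigenvector signs
    are fixed so each column's largest-magnitude entry is positive.
    """
    n = D.n
    if not 1 <= m <= n - 1:
        raise ValueError(f"m must be in [1, {n - 1}], got {m}")
    d2 = D.values**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(w)[::-1][:m]
    eigvals = w[order]
    vecs = v[:, order]
    # deterministic sign: largest-|entry| positive per eigenvector
    flip = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(m)])
    flip[flip == 0] = 1.0
    vecs = vecs * flip
    coords = vecs * np.sqrt(np.clip(eigvals, 0.0, None))
    # eigenvectors of near-zero eigenvalues can mix with the constant
    # direction numerically; enforce exact column centering
    coords = coords - coords.mean(axis=0)
    emb = ShapeEmbedding(coords, eigvals, list(D.subject_ids))
    try:
        emb.fidelity_r = embedding_fidelity(emb, D)
    except DegenerateStatisticError:
        emb.fidelity_r = None  # fewer than 3 subjects or constant distances
    return emb


def isomap(D: DistanceMatrix, k: int = 10, m: int = 20, auto_expand_k: bool = True) -> ShapeEmbedding:
    """Full ISOMAP: geodesic distances then classical scaling.

    ``fidelity_r`` is reported against the geodesic distance matrix (the
    standard ISOMAP residual convention); call
    ``embedding_fidelity(E, D)`` with the raw metric matrix for the
    metric-space fidelity. A disconnected k-NN graph doubles k with a
    logged warning unless ``auto_expand_k`` is False.
    """
    while True:
        try:
            geo = geodesic_distances(D, k)
            break
        except DisconnectedGraphError:
            if not auto_expand_k or k >= D.n - 1:
                raise
            log.warning("k-NN graph disconnected at k=%d; retrying with k=%d", k, 2 * k)
            k = min(2 * k, D.n - 1)
    emb = classical_scaling(geo, m)
    emb.neighbors_k = k
    return emb


def embedding_fidelity(E: ShapeEmbedding, D: DistanceMatrix) -> float:
    """Pearson correlation between upper-triangle embedded Euclidean
    distances and the corresponding entries of D."""
    if E.coordinates.shape[0] != D.n:
        raise ValueError("embedding and distance matrix cover different subjects")
    diff = E.coordinates[:, None, :] - E.coordinates[None, :, :]
    emb_d = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(D.n, k=1)
    x, y = emb_d[iu], D.values[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateStatisticError("constant distances: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def component_volume_correlation(E: ShapeEmbedding, volumes) -> list[tuple[float, float]]:
    """Pearson (r, two-tailed p) of each component against subject volumes."""
    volumes = np.asarray(volumes, dtype=float)
    if len(volumes) != E.coordinates.shape[0]:
        raise ValueError("volumes and embedding cover different subjects")
    if len(volumes) < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    out = []
    for c in range(E.n_components):
        col = E.coordinates[:, c]
        if np.ptp(col) == 0 or np.ptp(volumes) == 0:
            raise DegenerateStatisticError("constant input: correlation undefined")
        r, p = stats.pearsonr(col, volumes)
        out.append((float(r), float(p)))
    return out
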