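"""Mapping-fidelity metrics: the area score and the neighbor score.

The area score is the Pearson correlation between per-triangle areas
measured in 3-D and re-measured under the 2-D map (-1..1); the
neighbor score is the Tanimoto coefficient between k-nearest-neighbor
connectivity bit vectors, with 3-D neighborhoods taken geodesically
along the surface (mesh edge graph) and 2-D neighborhoods by
Euclidean distance in the map plane (0..1). The connectivity
matrices are directed (row i marks i's k nearest points) and are
linearized as-is; union symmetrization is available as an option.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .embeddings import geodesic_distances
from .types import (
    ArgumentError,
    ConnectivityBits,
    Embedding2D,
    ScoreReport,
    TriMesh3D,
    UndefinedScoreError,
)


def triangle_areas(points: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-face areas for 2-D or 3-D point sets (squared length units).

    Half the magnitude of the edge cross product; degenerate faces give
    zero.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] not in (2, 3):
        raise ArgumentError("points must be (n, 2) or (n, 3)")
    if p.shape[1] == 2:
        p = np.column_stack([p, np.zeros(len(p))])
    f = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    a = p[f[:, 1]] - p[f[:, 0]]
    b = p[f[:, 2]] - p[f[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def area_score(mesh: TriMesh3D, emb: Embedding2D) -> float:
    """Pearson r between 3-D triangle areas and their 2-D counterparts."""
    if emb.n_points != mesh.n_vertices:
        raise ArgumentError("embedding is not aligned with the mesh")
    if mesh.n_faces < 3:
        raise ArgumentError("need at least 3 faces for a correlation")
    a3 = triangle_areas(mesh.vertices, mesh.faces)
    a2 = triangle_areas(emb.coords, mesh.faces)
    if np.ptp(a3) == 0.0 or np.ptp(a2) == 0.0:
        raise UndefinedScoreError("zero variance in a triangle-area vector")
    return float(pearsonr(a3, a2).statistic)


def _knn_bits(
    distances: np.ndarray, k: int, symmetrize: bool = False
) -> ConnectivityBits:
    """Mark each point's k nearest others (ties broken by ascending
    index) and linearize the connectivity matrix as a bit vector.

    By default the directed matrix is linearized row-major without the
    diagonal; with ``symmetrize=True`` it is union-symmetrized first
    and linearized over unordered pairs.
    """
    d = np.asarray(distances, dtype=float)
    n = len(d)
    if k < 1 or k >= n:
        raise ArgumentError("need 1 <= k < n")
    # Quantize to 12 relative digits so exact geometric ties (common on
    # regular meshes) are broken by vertex index rather than by
    # floating-point noise, keeping the bits invariant under rigid
    # motions of the coordinates.
    scale = d.max()
    if scale > 0:
        d = np.round(d / scale, 12) * scale
    adj = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        row = d[i].copy()
        row[i] = np.inf
        order = np.lexsort((idx, row))  # distance first, index breaks ties
        adj[i, order[:k]] = True
    if symmetrize:
        adj |= adj.T
        bits = adj[np.triu_indices(n, k=1)]
    else:
        bits = adj[~np.eye(n, dtype=bool)]
    return ConnectivityBits(n=n, k=k, bits=bits, symmetric=symmetrize)


def knn_connectivity_3d(
    mesh: TriMesh3D, k: int = 3, symmetrize: bool = False
) -> ConnectivityBits:
    """Geodesic k-nearest-neighbor connectivity on the surface."""
    return _knn_bits(geodesic_distances(mesh), k, symmetrize)


def knn_connectivity_2d(
    emb: Embedding2D, k: int = 3, symmetrize: bool = False
) -> ConnectivityBits:
    """Euclidean k-nearest-neighbor connectivity in the map plane."""
    return _knn_bits(squareform(pdist(emb.coords)), k, symmetrize)


def tanimoto(x, y) -> float:
    """Tanimoto coefficient T = X.Y / (|X|^2 + |Y|^2 - X.Y) of two bit
    vectors; equals the Jaccard similarity of the marked-pair sets.
    Both-empty is defined as 1."""
    bx = x.bits if isinstance(x, ConnectivityBits) else np.asarray(x, dtype=bool)
    by = y.bits if isinstance(y, ConnectivityBits) else np.asarray(y, dtype=bool)
    if len(bx) != len(by):
        raise ArgumentError("bit vectors differ in length or pair ordering")
    inter = int(np.count_nonzero(bx & by))
    nx = int(np.count_nonzero(bx))
    ny = int(np.count_nonzero(by))
    denom = nx + ny - inter
    if denom == 0:
        return 1.0
    return inter / denom


def neighbor_score(
    mesh: TriMesh3D, emb: Embedding2D, k: int = 3, symmetrize: bool = False
) -> float:
    """Tanimoto similarity of 3-D geodesic and 2-D Euclidean k-NN bits."""
    if emb.n_points != mesh.n_vertices:
        raise ArgumentError("embedding is not aligned with the mesh")
    return tanimoto(
        knn_connectivity_3d(mesh, k, symmetrize),
        knn_connectivity_2d(emb, k, symmetrize),
    )


def score_embedding(mesh: TriMesh3D, emb: Embedding2D, k: int = 3) -> ScoreReport:
    """Area and neighbor scores bundled for one (mesh, embedding) pair."""
    return ScoreReport(
        area_score=area_score(mesh, emb),
        neighbor_score=neighbor_score(mesh, emb, k),
        k=k,
        method=emb.method,
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
    )
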