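"""2-D embeddings of surface meshes.

The panel covers the flattening methods that matter for molecular
cartography: linear projection (PCA), classical scaling of Euclidean
(MDS) and geodesic (Isomap, landmark Isomap) distances, Sammon's
stress minimization, stochastic neighbor embedding (SNE), and the
equal-area sinusoidal cartographic projection as the geographic
baseline.

Geodesic distances are shortest paths over the mesh's own edge graph,
weighted by 3-D edge length: the triangulation *is* the surface
topology, so no k-NN graph is built (that choice avoids shortcut
edges through the solvent).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import pdist, squareform

from .types import (
    ArgumentError,
    DegenerateEmbeddingError,
    DisconnectedMeshError,
    Embedding2D,
    TriMesh3D,
)

_RANK_RTOL = 1e-10


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: per axis, the largest-magnitude
    coordinate is made positive."""
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def _pca_coords(vertices: np.ndarray) -> np.ndarray:
    x = vertices - vertices.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    if len(s) < 2 or s[1] <= _RANK_RTOL * s[0]:
        raise DegenerateEmbeddingError("geometry has rank < 2")
    return _fix_signs(u[:, :2] * s[:2])


def embed_pca(mesh: TriMesh3D) -> Embedding2D:
    """Project centered vertices onto the top two principal axes."""
    return Embedding2D(coords=_pca_coords(mesh.vertices), method="pca")


def classical_scaling(distances: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson classical scaling of a symmetric distance matrix.

    Double-centers the squared distances and embeds on the top
    eigenvectors scaled by the square roots of their eigenvalues.
    """
    d = np.asarray(distances, dtype=float)
    n = len(d)
    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:n_components]
    w_top = w[order]
    if len(w_top) < n_components or w_top[n_components - 1] <= _RANK_RTOL * max(
        w_top[0], 1.0
    ):
        raise DegenerateEmbeddingError("distance matrix has rank < 2")
    return _fix_signs(v[:, order] * np.sqrt(w_top))


def embed_mds(mesh: TriMesh3D) -> Embedding2D:
    """Classical (Torgerson) scaling of the Euclidean distance matrix.

    Equivalent to PCA up to an orthogonal transform.
    """
    d = squareform(pdist(mesh.vertices))
    return Embedding2D(coords=classical_scaling(d), method="mds")


def _edge_graph(mesh: TriMesh3D) -> csr_matrix:
    edges = mesh.edges()
    lengths = mesh.edge_lengths(edges)
    n = mesh.n_vertices
    g = csr_matrix(
        (np.r_[lengths, lengths], (np.r_[edges[:, 0], edges[:, 1]],
                                   np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n),
    )
    return g


def _steiner_graph(mesh: TriMesh3D, m: int):
    """Edge graph refined with ``m`` Steiner points per edge.

    Every triangle becomes a clique over its corners and edge points,
    with straight-segment weights (a segment between two points on the
    edges of one triangle lies in that triangle, so its 3-D length is
    the exact surface distance). Paths may then cross face interiors
    instead of zigzagging along mesh edges, which removes most of the
    lattice anisotropy of the raw graph metric.
    """
    v = mesh.vertices
    n = mesh.n_vertices
    edges = mesh.edges()
    pts = [v]
    edge_nodes = {}
    nid = n
    ts = np.linspace(0.0, 1.0, m + 2)[1:-1]
    for a, b in edges:
        ids = list(range(nid, nid + m))
        pts.append(v[a] * (1 - ts)[:, None] + v[b] * ts[:, None])
        edge_nodes[(a, b)] = ids
        nid += m
    p = np.vstack(pts)

    rows, cols = [], []
    for f in mesh.faces:
        nodes = [f[0], f[1], f[2]]
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            nodes.extend(edge_nodes[(min(a, b), max(a, b))])
        nodes = np.asarray(nodes)
        ii, jj = np.triu_indices(len(nodes), 1)
        rows.append(nodes[ii])
        cols.append(nodes[jj])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    # Shared-edge pairs appear once per adjacent face: deduplicate so
    # sparse assembly does not sum their weights.
    lo = np.minimum(rows, cols)
    hi = np.maximum(rows, cols)
    _, keep = np.unique(lo * nid + hi, return_index=True)
    lo, hi = lo[keep], hi[keep]
    vals = np.linalg.norm(p[lo] - p[hi], axis=1)
    g = csr_matrix(
        (np.r_[vals, vals], (np.r_[lo, hi], np.r_[hi, lo])), shape=(nid, nid)
    )
    return g


def geodesic_distances(
    mesh: TriMesh3D,
    sources: Optional[np.ndarray] = None,
    edge_subdivisions: int = 0,
) -> np.ndarray:
    """Surface geodesic distances between mesh vertices (Angstroms).

    With ``edge_subdivisions=0`` these are shortest paths over the
    mesh's own edge graph, weighted by 3-D edge length. A positive
    value inserts that many Steiner points per edge and lets paths
    cross face interiors, converging toward the true polyhedral
    surface metric (used by the Isomap embeddings, which need the
    surface metric rather than the lattice metric). With ``sources``
    given, only those rows are computed.
    """
    g = (
        _edge_graph(mesh)
        if edge_subdivisions <= 0
        else _steiner_graph(mesh, int(edge_subdivisions))
    )
    n_comp, labels = connected_components(g, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels[: mesh.n_vertices])
        raise DisconnectedMeshError(
            f"mesh edge graph has {n_comp} components; vertex component "
            f"sizes {sizes.tolist()}"
        )
    if sources is None:
        indices = np.arange(mesh.n_vertices)
    else:
        indices = np.asarray(sources, dtype=np.int64)
    d = dijkstra(g, directed=False, indices=indices)
    if d.ndim == 1:
        return d[: mesh.n_vertices]
    return d[:, : mesh.n_vertices]


def embed_isomap(mesh: TriMesh3D, edge_subdivisions: int = 3) -> Embedding2D:
    """Classical scaling of the all-pairs geodesic distance matrix."""
    d = geodesic_distances(mesh, edge_subdivisions=edge_subdivisions)
    return Embedding2D(
        coords=classical_scaling(d),
        method="isomap",
        params={"edge_subdivisions": edge_subdivisions},
    )


def embed_landmark_isomap(
    mesh: TriMesh3D,
    n_landmarks: int = 50,
    seed: int = 0,
    edge_subdivisions: int = 3,
) -> Embedding2D:
    """Landmark Isomap: geodesics from a random landmark subset only.

    The landmarks are embedded by classical scaling of their mutual
    geodesic distances; every vertex is then placed by distance-based
    triangulation against the landmark embedding (the standard landmark
    MDS out-of-sample formula), which reproduces the landmark positions
    exactly and equals full Isomap when every vertex is a landmark.
    """
    n = mesh.n_vertices
    n_landmarks = int(n_landmarks)
    if n_landmarks < 3 or n_landmarks > n:
        raise ArgumentError("n_landmarks must be in [3, n_vertices]")
    rng = np.random.default_rng(seed)
    landmarks = np.sort(rng.choice(n, size=n_landmarks, replace=False))

    d_from_landmarks = geodesic_distances(
        mesh, sources=landmarks, edge_subdivisions=edge_subdivisions
    )  # (L, n)
    d_ll = d_from_landmarks[:, landmarks]

    d2 = d_ll**2
    m = len(landmarks)
    j = np.eye(m) - np.ones((m, m)) / m
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:2]
    w_top = w[order]
    if w_top[1] <= _RANK_RTOL * max(w_top[0], 1.0):
        raise DegenerateEmbeddingError("landmark distance matrix has rank < 2")
    l_emb = v[:, order] * np.sqrt(w_top)  # (L, 2)

    # Distance-based triangulation of all vertices against the landmarks.
    pseudo = v[:, order] / np.sqrt(w_top)  # (L, 2)
    mean_d2 = d2.mean(axis=0)  # (L,)
    coords = -0.5 * (d_from_landmarks**2 - mean_d2[:, None]).T @ pseudo
    # Landmarks land exactly on their classical-scaling positions.
    coords[landmarks] = l_emb
    coords = _fix_signs(coords)
    return Embedding2D(
        coords=coords,
        method="landmark-isomap",
        params={"n_landmarks": n_landmarks},
        seed=seed,
    )


def sammon_stress(d_high: np.ndarray, coords: np.ndarray) -> float:
    """Sammon stress E = (1/sum d) * sum (d - delta)^2 / d over pairs."""
    d_low = pdist(coords)
    return float(np.sum((d_high - d_low) ** 2 / d_high) / d_high.sum())


def embed_sammon(
    mesh: TriMesh3D,
    max_iter: int = 500,
    tolerance: float = 1e-7,
    init: Optional[np.ndarray] = None,
) -> Embedding2D:
    """Sammon mapping: iterative descent on Sammon's stress from PCA.

    Uses the classic diagonal-Newton update with step halving, so the
    reported stress never increases across accepted steps. Stops when
    the relative stress change drops below ``tolerance`` or after
    ``max_iter`` iterations.
    """
    d_high = pdist(mesh.vertices)
    if np.any(d_high == 0.0):
        raise ArgumentError("duplicate vertices give infinite Sammon weights")
    y = _pca_coords(mesh.vertices) if init is None else np.array(init, dtype=float)

    c = d_high.sum()
    dh = squareform(d_high)
    np.fill_diagonal(dh, 1.0)  # placeholder, masked below
    n = len(y)
    eye = np.eye(n, dtype=bool)

    stress = sammon_stress(d_high, y)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        diff = y[:, None, :] - y[None, :, :]  # (n, n, 2)
        dl = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dl, 1.0)
        dl = np.maximum(dl, 1e-12)

        inv = 1.0 / (dh * dl)
        inv[eye] = 0.0
        delta = dh - dl
        delta[eye] = 0.0

        grad = -2.0 / c * np.einsum("ij,ijk->ik", delta * inv, diff)
        h = delta * inv - (diff**2).transpose(2, 0, 1) * inv / dl * (
            1.0 + delta / dl
        )
        hess = -2.0 / c * h.sum(axis=2).T
        step = -grad / np.maximum(np.abs(hess), 1e-12)

        alpha = 0.3  # Sammon's magic factor
        new_stress = stress
        for _ in range(30):
            y_try = y + alpha * step
            s_try = sammon_stress(d_high, y_try)
            if s_try < stress:
                y, new_stress = y_try, s_try
                break
            alpha *= 0.5
        else:
            break  # no descent direction left
        if stress - new_stress < tolerance * max(stress, 1e-30):
            stress = new_stress
            break
        stress = new_stress

    return Embedding2D(
        coords=y,
        method="sammon",
        params={
            "max_iter": max_iter,
            "tolerance": tolerance,
            "stress": stress,
            "n_iter": n_iter,
        },
    )


def _conditional_probs(d2: np.ndarray, perplexity: float) -> np.ndarray:
    """Per-point Gaussian conditional probabilities p_{j|i} with the
    bandwidth of each point solved by bisection to match ``perplexity``."""
    n = len(d2)
    target_entropy = np.log(perplexity)
    p = np.zeros((n, n))
    for i in range(n):
        lo, hi = 1e-20, 1e20
        beta = 1.0  # precision 1/(2 sigma^2)
        row = np.delete(d2[i], i)
        for _ in range(100):
            ex = np.exp(-row * beta)
            s = ex.sum()
            if s <= 0:
                hi = beta
                beta = (lo + hi) / 2.0
                continue
            probs = ex / s
            entropy = -(probs * np.log(np.maximum(probs, 1e-300))).sum()
            if abs(entropy - target_entropy) < 1e-7:
                break
            if entropy > target_entropy:
                lo = beta
            else:
                hi = beta
            beta = (lo + hi) / 2.0
        else:
            if not np.isfinite(entropy):
                raise ArgumentError(f"bandwidth bisection failed at vertex {i}")
        p[i, np.arange(n) != i] = probs
    return p


def _sne_cost_grad(p: np.ndarray, y: np.ndarray):
    n = len(y)
    diff = y[:, None, :] - y[None, :, :]
    d2 = (diff**2).sum(-1)
    ex = np.exp(-d2)
    np.fill_diagonal(ex, 0.0)
    q = ex / np.maximum(ex.sum(axis=1, keepdims=True), 1e-300)
    q = np.maximum(q, 1e-300)
    mask = ~np.eye(n, dtype=bool)
    cost = float(np.sum(p[mask] * np.log(np.maximum(p[mask], 1e-300) / q[mask])))
    m = (p - q) + (p - q).T
    grad = 2.0 * np.einsum("ij,ijk->ik", m, diff)
    return cost, grad


def embed_sne(
    mesh: TriMesh3D,
    perplexity: float = 15.0,
    n_iter: int = 1000,
    learning_rate: float = 10.0,
    seed: int = 0,
) -> Embedding2D:
    """Stochastic neighbor embedding of the 3-D vertex cloud.

    Gaussian conditional neighbor probabilities are computed in 3-D
    with per-point bandwidths matched to ``perplexity``; 2-D positions
    start from seeded small Gaussian noise and descend the summed
    Kullback-Leibler divergence by gradient descent with momentum
    (0.5 for the first quarter of the schedule, 0.8 after). The final
    KL cost is stored in ``params['kl_cost']``.
    """
    n = mesh.n_vertices
    if n < 3 * perplexity:
        raise ArgumentError("need n_vertices >= 3 * perplexity")
    d2 = squareform(pdist(mesh.vertices)) ** 2
    p = _conditional_probs(d2, perplexity)

    rng = np.random.default_rng(seed)
    y = rng.normal(scale=1e-4, size=(n, 2))
    update = np.zeros_like(y)
    cost, grad = _sne_cost_grad(p, y)
    lr = learning_rate
    for it in range(n_iter):
        momentum = 0.5 if it < n_iter // 4 else 0.8
        # Backtracking keeps the KL cost non-increasing: halve the step
        # (and drop momentum) whenever a trial step overshoots.
        accepted = False
        for _ in range(50):
            trial_update = momentum * update - lr * grad
            y_try = y + trial_update
            y_try = y_try - y_try.mean(axis=0)
            cost_try, grad_try = _sne_cost_grad(p, y_try)
            if cost_try <= cost:
                y, cost, grad, update = y_try, cost_try, grad_try, trial_update
                lr = min(lr * 1.1, learning_rate)
                accepted = True
                break
            lr *= 0.5
            update = np.zeros_like(y)
            momentum = 0.0
        if not accepted:
            break

    return Embedding2D(
        coords=y,
        method="sne",
        params={
            "perplexity": perplexity,
            "n_iter": n_iter,
            "learning_rate": learning_rate,
            "kl_cost": cost,
        },
        seed=seed,
    )


def project_sinusoidal(mesh: TriMesh3D) -> Embedding2D:
    """Equal-area sinusoidal cartographic projection.

    Vertices are converted to spherical coordinates (latitude phi,
    longitude lam) about the vertex centroid and mapped to
    ``x = R * (lam - lam0) * cos(phi)``, ``y = R * phi`` with R the
    mean radial distance and lam0 the circular-mean longitude;
    longitude differences are wrapped to (-pi, pi].
    """
    c = mesh.centroid()
    rel = mesh.vertices - c
    r = np.linalg.norm(rel, axis=1)
    if np.any(r == 0.0):
        raise ArgumentError("a vertex coincides with the centroid")
    phi = np.arcsin(np.clip(rel[:, 2] / r, -1.0, 1.0))
    lam = np.arctan2(rel[:, 1], rel[:, 0])
    lam0 = np.arctan2(np.sin(lam).mean(), np.cos(lam).mean())
    dlam = np.mod(lam - lam0 + np.pi, 2.0 * np.pi) - np.pi
    r_bar = r.mean()
    coords = np.column_stack([r_bar * dlam * np.cos(phi), r_bar * phi])
    return Embedding2D(coords=coords, method="sinusoidal")


#: Deterministic + stochastic method registry used by the CLI benchmark.
METHODS = {
    "pca": embed_pca,
    "mds": embed_mds,
    "sammon": embed_sammon,
    "isomap": embed_isomap,
    "landmark-isomap": embed_landmark_isomap,
    "sne": embed_sne,
    "sinusoidal": project_sinusoidal,
}


def embed(mesh: TriMesh3D, method: str, seed: int = 0, **params) -> Embedding2D:
    """Dispatch to one of the panel methods by name."""
    if method not in METHODS:
        raise ArgumentError(
            f"unknown method {method!r}; panel: {sorted(METHODS)}"
        )
    fn = METHODS[method]
    if method in ("sne", "landmark-isomap"):
        return fn(mesh, seed=seed, **params)
    return fn(mesh, **params)
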