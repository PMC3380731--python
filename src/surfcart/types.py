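"""Core data containers shared across the surface-cartography pipeline.

Coordinates are Angstroms throughout; 2-D map coordinates are unitless
map units. Faces are 0-based vertex-index triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class SurfcartError(Exception):
    """Base class for pipeline errors."""


class ArgumentError(SurfcartError, ValueError):
    """Invalid argument combination."""


class FormatError(SurfcartError, ValueError):
    """Malformed input file."""


class EmptySectionError(SurfcartError):
    """A half-space cut retained zero faces."""


class DegenerateEmbeddingError(SurfcartError):
    """Geometry of rank < 2 cannot be embedded in the plane."""


class DisconnectedMeshError(SurfcartError):
    """Geodesic routines require a connected edge graph."""


class UndefinedScoreError(SurfcartError):
    """A fidelity score is undefined (zero variance input)."""


@dataclass
class TriMesh3D:
    """Triangulated 3-D surface.

    Parameters
    ----------
    vertices : (n, 3) float array, Angstroms.
    faces : (m, 3) int array of 0-based vertex indices.
    atom_index : optional (n,) int array; 1-based index of the nearest
        atom for each vertex, as reported by MSMS.
    normals : optional (n, 3) float array of per-vertex unit normals.
    """

    vertices: np.ndarray
    faces: np.ndarray
    atom_index: Optional[np.ndarray] = None
    normals: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertices.shape[1] != 3:
            raise ArgumentError("vertices must be an (n, 3) array")
        n = len(self.vertices)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= n:
                raise ArgumentError("face index out of vertex range")
            if np.any(
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            ):
                raise ArgumentError("a face repeats a vertex")
        if self.atom_index is not None:
            self.atom_index = np.asarray(self.atom_index, dtype=np.int64)
            if len(self.atom_index) != n:
                raise ArgumentError("atom_index length must match vertex count")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(n, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a sorted (n_edges, 2) int array."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self, edges: Optional[np.ndarray] = None) -> np.ndarray:
        if edges is None:
            edges = self.edges()
        d = self.vertices[edges[:, 0]] - self.vertices[edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def vertex_normals(self) -> np.ndarray:
        """Per-vertex unit normals.

        Returns stored normals when present; otherwise area-weighted
        averages of incident face normals (assumes consistent outward
        winding of the faces).
        """
        if self.normals is not None:
            return self.normals
        a = self.vertices[self.faces[:, 1]] - self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 2]] - self.vertices[self.faces[:, 0]]
        fn = np.cross(a, b)  # magnitude = 2 * face area
        vn = np.zeros_like(self.vertices)
        for c in range(3):
            np.add.at(vn, self.faces[:, c], fn)
        norms = np.linalg.norm(vn, axis=1)
        norms[norms == 0] = 1.0
        return vn / norms[:, None]


@dataclass
class Embedding2D:
    """Per-vertex 2-D map coordinates aligned with a source mesh.

    ``coords[i]`` is the planar position of mesh vertex ``i``; the
    method tag, parameters and seed are retained so a deterministic
    embedding can be regenerated.
    """

    coords: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.coords)):
            raise ArgumentError("embedding coordinates must be finite")

    @property
    def n_points(self) -> int:
        return len(self.coords)


@dataclass
class FeatureField:
    """Per-vertex scalar channel (hydrophobicity, potential, curvature...).

    ``clip_range`` is the (lo, hi) pair used to normalize the channel
    for display; values outside it are clipped when rasterized.
    """

    values: np.ndarray
    kind: str
    clip_range: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ArgumentError("feature values must be finite")
        if self.clip_range is None:
            lo, hi = float(self.values.min()), float(self.values.max())
            if lo == hi:
                hi = lo + 1.0
            self.clip_range = (lo, hi)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ScoreReport:
    """Mapping-fidelity summary for one (mesh, embedding) pair."""

    area_score: float
    neighbor_score: float
    k: int
    method: str
    n_vertices: int
    n_faces: int

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.area_score <= 1.0 + 1e-9):
            raise ArgumentError("area score outside [-1, 1]")
        if not (-1e-9 <= self.neighbor_score <= 1.0 + 1e-9):
            raise ArgumentError("neighbor score outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "area_score": self.area_score,
            "neighbor_score": self.neighbor_score,
            "k": self.k,
            "n_vertices": self.n_vertices,
            "n_faces": self.n_faces,
        }


@dataclass
class ConnectivityBits:
    """k-nearest-neighbor connectivity matrix linearized as a bit vector.

    Row ``i`` of the underlying matrix marks the k nearest other
    vertices of ``i`` (directed: nearness is not mutual). The matrix
    is linearized row-major with the diagonal dropped, giving
    ``n * (n - 1)`` bits; set ``symmetric=True`` when the bits come
    from a union-symmetrized matrix over unordered pairs
    (``n * (n - 1) / 2`` bits).
    """

    n: int
    k: int
    bits: np.ndarray
    symmetric: bool = False

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool).ravel()
        expected = self.n * (self.n - 1) // (2 if self.symmetric else 1)
        if len(self.bits) != expected:
            raise ArgumentError(
                f"bit vector length {len(self.bits)} != expected {expected}"
            )
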