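"""Analytic test meshes: icospheres, half-space cuts and cylinder patches.

These fixtures mirror the geometry used to benchmark surface flattening:
a subdivided icosahedron gives a sphere with near-equidistant points, a
half-space cut of it gives the reference hemisphere, and an open
cylinder sector is an exactly developable surface whose flattening is
known in closed form.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np

from .types import ArgumentError, EmptySectionError, TriMesh3D

_PHI = (1.0 + math.sqrt(5.0)) / 2.0

# Cyclic (+-1, +-phi, 0) icosahedron; faces wound counter-clockwise seen
# from outside so vertex normals point outward.
_ICO_VERTICES = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=float,
)

_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)

_AXES = {"x": 0, "y": 1, "z": 2}


def make_icosphere(subdivision_level: int) -> TriMesh3D:
    """Unit sphere obtained by subdividing an icosahedron.

    Each subdivision splits every triangle in four at deduplicated edge
    midpoints and projects all vertices to the unit sphere, giving
    ``10 * 4**level + 2`` vertices and ``20 * 4**level`` faces.

    Parameters
    ----------
    subdivision_level : int
        Number of 1-to-4 refinements, 0 <= level <= 6.
    """
    level = int(subdivision_level)
    if level < 0:
        raise ArgumentError("subdivision level must be non-negative")
    if level > 6:
        raise ArgumentError("subdivision level > 6 refused (mesh explosion)")

    vertices = [v / np.linalg.norm(v) for v in _ICO_VERTICES]
    faces = _ICO_FACES.copy()

    for _ in range(level):
        midpoint_cache: dict = {}
        new_faces = []

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            idx = midpoint_cache.get(key)
            if idx is None:
                m = vertices[i] + vertices[j]
                m /= np.linalg.norm(m)
                idx = len(vertices)
                vertices.append(m)
                midpoint_cache[key] = idx
            return idx

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = np.array(new_faces, dtype=np.int64)

    return TriMesh3D(vertices=np.array(vertices), faces=faces)


def cut_halfspace(
    mesh: TriMesh3D,
    axis: str,
    sign: str,
    origin: Optional[np.ndarray] = None,
) -> Tuple[TriMesh3D, np.ndarray]:
    """Keep only the faces lying entirely inside one coordinate half-space.

    A face survives when all three of its vertices satisfy
    ``sign * (coord - origin_coord) >= 0``; vertices exactly on the
    plane count for both half-spaces, and faces straddling the plane
    are dropped (no edge clipping). Unreferenced vertices are removed.

    Returns
    -------
    (section, vertex_map) : the cut mesh and an int array giving, for
        each new vertex, its index in the input mesh.
    """
    if axis not in _AXES:
        raise ArgumentError(f"axis must be one of x/y/z, got {axis!r}")
    s = {"+": 1.0, "-": -1.0, "+1": 1.0, "-1": -1.0}.get(str(sign))
    if s is None:
        s = 1.0 if float(sign) > 0 else -1.0
    if origin is None:
        origin = mesh.centroid()
    origin = np.asarray(origin, dtype=float).ravel()

    ax = _AXES[axis]
    ok = s * (mesh.vertices[:, ax] - origin[ax]) >= 0.0
    keep = ok[mesh.faces].all(axis=1)
    if not keep.any():
        raise EmptySectionError(f"no face lies in the {sign}{axis} half-space")

    faces = mesh.faces[keep]
    vertex_map = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[vertex_map] = np.arange(len(vertex_map))

    section = TriMesh3D(
        vertices=mesh.vertices[vertex_map],
        faces=remap[faces],
        atom_index=None if mesh.atom_index is None else mesh.atom_index[vertex_map],
        normals=None if mesh.normals is None else mesh.normals[vertex_map],
    )
    return section, vertex_map


def _grid_samples(n: int, extent: float, graded: bool) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    if graded:
        # Smooth monotone densification toward one end; keeps the patch
        # developable while giving the triangle areas real variance
        # (a perfectly uniform grid has constant areas, which makes an
        # area correlation degenerate).
        t = t**1.5
    return extent * t


def make_cylinder_patch(
    radius: float,
    height: float,
    n_u: int,
    n_v: int,
    angular_extent: float,
    graded: bool = False,
) -> TriMesh3D:
    """Open cylinder sector on an (n_u x n_v) grid.

    The patch spans ``theta in [0, angular_extent]`` and
    ``z in [0, height]``; it is isometrically developable to the plane
    (``u = R * theta``, ``v = z``), which makes it an exact oracle for
    flattening methods. With ``graded=True`` the grid spacing is
    smoothly non-uniform so the triangle areas vary (a uniform grid
    has constant areas, on which an area correlation is undefined).
    """
    if n_u < 2 or n_v < 2:
        raise ArgumentError("n_u and n_v must be >= 2")
    if not (0.0 < angular_extent < 2.0 * math.pi):
        raise ArgumentError("angular extent must lie strictly in (0, 2*pi)")
    if radius <= 0 or height <= 0:
        raise ArgumentError("radius and height must be positive")

    theta = _grid_samples(n_u, angular_extent, graded)
    z = _grid_samples(n_v, height, graded)
    tt, zz = np.meshgrid(theta, z, indexing="ij")
    vertices = np.column_stack(
        [radius * np.cos(tt).ravel(), radius * np.sin(tt).ravel(), zz.ravel()]
    )

    faces = []
    for i in range(n_u - 1):
        for j in range(n_v - 1):
            v00 = i * n_v + j
            v01 = v00 + 1
            v10 = v00 + n_v
            v11 = v10 + 1
            faces.append((v00, v10, v11))
            faces.append((v00, v11, v01))
    return TriMesh3D(vertices=vertices, faces=np.array(faces, dtype=np.int64))


def develop_cylinder_patch(
    radius: float,
    height: float,
    n_u: int,
    n_v: int,
    angular_extent: float,
    graded: bool = False,
) -> np.ndarray:
    """Analytic planar development of :func:`make_cylinder_patch`.

    Returns (n_u * n_v, 2) coordinates ``(R * theta, z)`` in the same
    vertex order as the mesh; the unrolling is an isometry of the
    smooth sector, so edge lengths are preserved up to chord-vs-arc
    discretization.
    """
    theta = _grid_samples(n_u, angular_extent, graded)
    z = _grid_samples(n_v, height, graded)
    tt, zz = np.meshgrid(theta, z, indexing="ij")
    return np.column_stack([radius * tt.ravel(), zz.ravel()])
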