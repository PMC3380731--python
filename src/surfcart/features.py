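"""Per-vertex biochemical and geometric surface channels.

Three channels enrich a surface map: Kyte-Doolittle hydrophobicity of
the residue owning each surface point, electrostatic potential (a
screened-Coulomb model with distance-dependent dielectric, or an
imported externally solved grid), and discrete mean curvature from the
cotangent Laplace-Beltrami operator. A 0/1 annotation mask highlights
user-listed residues (e.g. an active site).
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .types import ArgumentError, FeatureField, FormatError, TriMesh3D
from .surface_io import Structure

#: Kyte-Doolittle hydropathy index per residue (dimensionless,
#: -4.5 = most hydrophilic Arg, +4.5 = most hydrophobic Ile).
KYTE_DOOLITTLE: Dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

#: Formal charges (elementary charge units) placed on representative
#: side-chain atoms; termini handled separately.
FORMAL_CHARGES: Dict[str, Tuple[str, float]] = {
    "ASP": ("CG", -1.0),
    "GLU": ("CD", -1.0),
    "LYS": ("NZ", 1.0),
    "ARG": ("CZ", 1.0),
    "HIS": ("ND1", 0.1),
}


def _vertex_atom_indices(
    structure: Structure, mesh: TriMesh3D, cutoff: float = 5.0
) -> np.ndarray:
    """0-based index of the atom owning each vertex.

    Uses the MSMS-reported nearest-atom index when the mesh carries
    one, otherwise a nearest-neighbor search limited to ``cutoff``
    Angstroms.
    """
    n_atoms = len(structure.atoms)
    if mesh.atom_index is not None:
        idx = mesh.atom_index - 1
        if idx.min() < 0 or idx.max() >= n_atoms:
            raise ArgumentError(
                "mesh atom_index does not fit the structure's atom count"
            )
        return idx
    tree = cKDTree(structure.coords())
    dist, idx = tree.query(mesh.vertices)
    too_far = np.nonzero(dist > cutoff)[0]
    if len(too_far):
        raise ArgumentError(
            f"vertex {too_far[0]} has no atom within {cutoff} A"
        )
    return idx


def kd_hydrophobicity(
    structure: Structure, mesh: TriMesh3D, cutoff: float = 5.0
) -> FeatureField:
    """Kyte-Doolittle hydropathy of the residue owning each vertex."""
    idx = _vertex_atom_indices(structure, mesh, cutoff)
    values = np.empty(mesh.n_vertices)
    for i, ai in enumerate(idx):
        resname = structure.atoms[ai].resname
        if resname not in KYTE_DOOLITTLE:
            raise ArgumentError(f"unknown residue name {resname!r}")
        values[i] = KYTE_DOOLITTLE[resname]
    return FeatureField(values=values, kind="hydrophobicity", clip_range=(-4.5, 4.5))


def assign_formal_charges(structure: Structure) -> List[Tuple[np.ndarray, float]]:
    """Default charge set: Asp/Glu side chains -1, Lys/Arg +1, His +0.1
    (placed on a representative side-chain atom), plus +1 on each
    chain's N-terminal nitrogen and -1 on its C-terminal carboxyl."""
    charges: List[Tuple[np.ndarray, float]] = []
    residues = structure.residues()
    for (chain, resnum, resname), atoms in residues:
        if resname in FORMAL_CHARGES:
            atom_name, q = FORMAL_CHARGES[resname]
            for a in atoms:
                if a.name == atom_name:
                    charges.append((a.coord, q))
                    break
    # Termini: first and last residue of each chain.
    by_chain: Dict[str, list] = {}
    for key, atoms in residues:
        by_chain.setdefault(key[0], []).append(atoms)
    for chain_residues in by_chain.values():
        for a in chain_residues[0]:
            if a.name == "N":
                charges.append((a.coord, 1.0))
                break
        last = chain_residues[-1]
        cterm = next(
            (a for a in last if a.name == "OXT"),
            next((a for a in last if a.name == "C"), None),
        )
        if cterm is not None:
            charges.append((cterm.coord, -1.0))
    return charges


def coulomb_potential(
    structure: Structure,
    mesh: TriMesh3D,
    charges: Optional[List[Tuple[np.ndarray, float]]] = None,
    min_distance: float = 1.0,
) -> FeatureField:
    """Screened Coulomb potential with distance-dependent dielectric.

    phi(v) = sum_i q_i / (eps(d_i) * d_i) with eps(d) = 4 d, i.e.
    q / (4 d^2), d in Angstroms floored at ``min_distance`` to guard
    against malformed inputs (surface vertices normally sit about a
    probe radius away from the nearest atom). Units are charge/A per
    dielectric unit; only relative surface patterns are meaningful.
    """
    if charges is None:
        charges = assign_formal_charges(structure)
    values = np.zeros(mesh.n_vertices)
    if charges:
        pos = np.array([c[0] for c in charges])
        q = np.array([c[1] for c in charges])
        d = np.linalg.norm(mesh.vertices[:, None, :] - pos[None, :, :], axis=2)
        if np.any(d <= 0.0):
            raise ArgumentError("a vertex coincides with a charge site")
        d = np.maximum(d, min_distance)
        values = (q[None, :] / (4.0 * d**2)).sum(axis=1)
    lim = float(np.percentile(np.abs(values), 95)) or 1.0
    return FeatureField(values=values, kind="potential", clip_range=(-lim, lim))


# ------------------------------------------------------- OpenDX grids

class PotentialGrid:
    """Regular scalar grid in OpenDX layout (origin + spacings + data)."""

    def __init__(self, origin, delta, counts, values):
        self.origin = np.asarray(origin, dtype=float)
        self.delta = np.asarray(delta, dtype=float)
        self.counts = tuple(int(c) for c in counts)
        self.values = np.asarray(values, dtype=float).reshape(self.counts)

    def axes(self):
        return [
            self.origin[i] + self.delta[i] * np.arange(self.counts[i])
            for i in range(3)
        ]


def load_potential_grid(dx_path: str) -> PotentialGrid:
    """Parse an OpenDX scalar grid (the format external electrostatics
    solvers write their potentials in)."""
    counts = origin = None
    deltas: List[np.ndarray] = []
    data: List[float] = []
    n_expected = None
    with open(dx_path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            f = s.split()
            if s.startswith("object") and "gridpositions" in s:
                counts = [int(x) for x in f[-3:]]
            elif s.startswith("origin"):
                origin = [float(x) for x in f[1:4]]
            elif s.startswith("delta"):
                deltas.append(np.array([float(x) for x in f[1:4]]))
            elif s.startswith("object") and "array" in s:
                n_expected = int(f[f.index("items") + 1]) if "items" in f else None
            elif s.startswith(("attribute", "component", "object")):
                continue
            else:
                try:
                    data.extend(float(x) for x in f)
                except ValueError:
                    raise FormatError(f"unparseable OpenDX line: {s!r}")
    if counts is None or origin is None or len(deltas) != 3:
        raise FormatError("missing OpenDX header fields")
    diag = np.array([deltas[i][i] for i in range(3)])
    if np.any(diag <= 0) or not np.allclose(
        np.array(deltas), np.diag(diag)
    ):
        raise FormatError("only axis-aligned OpenDX grids are supported")
    n_total = counts[0] * counts[1] * counts[2]
    if n_expected is not None and n_expected != n_total:
        raise FormatError("OpenDX item count disagrees with grid counts")
    if len(data) != n_total:
        raise FormatError(
            f"expected {n_total} grid values, found {len(data)}"
        )
    return PotentialGrid(origin=origin, delta=diag, counts=counts, values=data)


def sample_potential(grid: PotentialGrid, mesh: TriMesh3D) -> FeatureField:
    """Trilinear interpolation of a potential grid at each vertex.

    Vertices outside the grid are clamped to the boundary value; a
    single warning reports how many were clamped.
    """
    from scipy.interpolate import RegularGridInterpolator

    axes = grid.axes()
    lo = np.array([a[0] for a in axes])
    hi = np.array([a[-1] for a in axes])
    pts = mesh.vertices
    outside = np.any((pts < lo) | (pts > hi), axis=1)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} vertices outside the potential grid;"
            " clamped to the boundary",
            stacklevel=2,
        )
    clamped = np.clip(pts, lo, hi)
    interp = RegularGridInterpolator(axes, grid.values)
    values = interp(clamped)
    lim = float(np.percentile(np.abs(values), 95)) or 1.0
    return FeatureField(values=values, kind="potential", clip_range=(-lim, lim))


# ---------------------------------------------------------- curvature

def _check_orientation(mesh: TriMesh3D) -> None:
    # Interior edges of a consistently oriented mesh appear once in
    # each direction.
    directed: Dict[Tuple[int, int], int] = {}
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (int(a), int(b))
            directed[key] = directed.get(key, 0) + 1
            if directed[key] > 1:
                raise ArgumentError("inconsistent face orientation")


def mean_curvature(mesh: TriMesh3D) -> FeatureField:
    """Signed discrete mean curvature (1/Angstrom) per vertex.

    Computed from the cotangent Laplace-Beltrami operator:
    ``H(v) = +-|Lap v| / (2 A_v)`` with barycentric vertex areas,
    positive where the mean-curvature vector opposes the outward
    normal (convex bulges) and negative in concavities. Boundary
    vertices, where the operator is unreliable, take the average of
    their interior one-ring neighbors.
    """
    _check_orientation(mesh)
    v = mesh.vertices
    n = mesh.n_vertices
    lap = np.zeros_like(v)
    areas = np.zeros(n)

    # Boundary vertices: endpoints of edges with a single incident face.
    edge_count: Dict[Tuple[int, int], int] = {}
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            edge_count[key] = edge_count.get(key, 0) + 1
    boundary = np.zeros(n, dtype=bool)
    for (a, b), c in edge_count.items():
        if c == 1:
            boundary[a] = boundary[b] = True

    for f in mesh.faces:
        cots = np.empty(3)
        for corner in range(3):
            i, j, k = f[corner], f[(corner + 1) % 3], f[(corner + 2) % 3]
            e1 = v[j] - v[i]
            e2 = v[k] - v[i]
            area2 = np.linalg.norm(np.cross(e1, e2))
            if area2 == 0:
                cots[:] = 0.0
                break
            cot = np.dot(e1, e2) / area2  # cot of angle at i
            cots[corner] = cot
            # Angle at i is opposite edge (j, k): cot weight splits onto it.
            lap[j] += 0.5 * cot * (v[k] - v[j])
            lap[k] += 0.5 * cot * (v[j] - v[k])
        if area2 == 0:
            continue
        # Meyer mixed-Voronoi vertex areas: Voronoi split for non-obtuse
        # triangles, half/quarter split when an angle is obtuse.
        face_area = area2 / 2.0
        if np.all(cots >= 0.0):
            for corner in range(3):
                i, j, k = f[corner], f[(corner + 1) % 3], f[(corner + 2) % 3]
                areas[i] += (
                    np.dot(v[j] - v[i], v[j] - v[i]) * cots[(corner + 2) % 3]
                    + np.dot(v[k] - v[i], v[k] - v[i]) * cots[(corner + 1) % 3]
                ) / 8.0
        else:
            obtuse = int(np.argmin(cots))
            for corner in range(3):
                areas[f[corner]] += (
                    face_area / 2.0 if corner == obtuse else face_area / 4.0
                )

    normals = mesh.vertex_normals()
    h = np.zeros(n)
    interior = ~boundary & (areas > 0)
    mag = np.linalg.norm(lap[interior], axis=1) / (2.0 * areas[interior])
    # Laplacian points toward the center of curvature; a convex vertex
    # (center inside) has it opposed to the outward normal.
    sign = -np.sign(np.einsum("ij,ij->i", lap[interior], normals[interior]))
    sign[sign == 0] = 1.0
    h[interior] = sign * mag

    if boundary.any():
        neighbors: Dict[int, set] = {i: set() for i in range(n)}
        for a, b in edge_count:
            neighbors[a].add(b)
            neighbors[b].add(a)
        for i in np.nonzero(boundary)[0]:
            ring = [j for j in neighbors[i] if interior[j]]
            h[i] = float(np.mean(h[ring])) if ring else 0.0

    lim = float(np.percentile(np.abs(h), 95)) or 1.0
    return FeatureField(values=h, kind="curvature", clip_range=(-lim, lim))


# ----------------------------------------------------------- annotation

def annotation_mask(
    residue_list: Sequence[Tuple[str, int]],
    structure: Structure,
    mesh: TriMesh3D,
    cutoff: float = 5.0,
) -> FeatureField:
    """0/1 mask of vertices whose owning atom lies in a listed residue.

    Residues absent from the structure are skipped with a warning.
    """
    present = {(chain, resnum) for (chain, resnum, _), _ in structure.residues()}
    wanted = set()
    for chain, resnum in residue_list:
        if (chain, resnum) not in present:
            warnings.warn(
                f"annotated residue {chain} {resnum} not in structure; skipped",
                stacklevel=2,
            )
            continue
        wanted.add((chain, resnum))
    idx = _vertex_atom_indices(structure, mesh, cutoff)
    values = np.array(
        [
            1.0
            if (structure.atoms[ai].chain, structure.atoms[ai].resnum) in wanted
            else 0.0
            for ai in idx
        ]
    )
    return FeatureField(values=values, kind="annotation", clip_range=(0.0, 1.0))
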