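"""Readers and writers for the formats the workflow touches.

MSMS .vert/.face pairs (triangulated solvent-excluded surfaces), PDB
coordinate files, ASCII PLY with optional per-vertex colors, PNG
rasters, and the plain-text residue-annotation list used for
active-site overlays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .types import ArgumentError, FormatError, TriMesh3D


# ---------------------------------------------------------------- MSMS

def _data_lines(path: str) -> List[Tuple[int, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            out.append((lineno, s))
    return out


def read_msms(vert_path: str, face_path: str) -> TriMesh3D:
    """Read a paired MSMS .vert/.face surface.

    Each vertex record carries x y z nx ny nz followed by integer
    fields whose meaning varies across MSMS versions; the second
    trailing integer is taken as the 1-based nearest-atom index.
    Face records carry three 1-based vertex indices (converted to
    0-based). The count header line is skipped; when it disagrees with
    the actual number of records a warning is issued and the records
    are trusted.
    """
    vlines = _data_lines(vert_path)
    flines = _data_lines(face_path)
    if not vlines or not flines:
        raise FormatError("empty MSMS file")

    def parse_vertex_block(lines):
        header_count = None
        records = []
        for lineno, s in lines:
            fields = s.split()
            if len(fields) < 6 and header_count is None and not records:
                try:
                    header_count = int(float(fields[0]))
                except (ValueError, IndexError):
                    raise FormatError(f"unparseable header at line {lineno}")
                continue
            try:
                floats = [float(f) for f in fields[:6]]
            except ValueError:
                raise FormatError(f"bad vertex record at line {lineno}")
            trailing = fields[6:]
            atom = int(trailing[1]) if len(trailing) >= 2 else 1
            records.append((floats, atom))
        return header_count, records

    header_count, vrecords = parse_vertex_block(vlines)
    if header_count is not None and header_count != len(vrecords):
        warnings.warn(
            f"vert header says {header_count} records, found {len(vrecords)};"
            " trusting the records",
            stacklevel=2,
        )

    vertices = np.array([r[0][:3] for r in vrecords])
    normals = np.array([r[0][3:6] for r in vrecords])
    atom_index = np.array([r[1] for r in vrecords], dtype=np.int64)
    n = len(vertices)

    faces = []
    fheader = None
    for lineno, s in flines:
        fields = s.split()
        if len(fields) < 3 and fheader is None and not faces:
            fheader = int(float(fields[0]))
            continue
        try:
            tri = [int(f) for f in fields[:3]]
        except ValueError:
            raise FormatError(f"bad face record at line {lineno}")
        for idx in tri:
            if not (1 <= idx <= n):
                raise FormatError(
                    f"face index {idx} out of range [1, {n}] at line "
                    f"{lineno} of {face_path}"
                )
        faces.append([i - 1 for i in tri])
    if fheader is not None and fheader != len(faces):
        warnings.warn(
            f"face header says {fheader} records, found {len(faces)};"
            " trusting the records",
            stacklevel=2,
        )
    return TriMesh3D(
        vertices=vertices,
        faces=np.array(faces, dtype=np.int64),
        atom_index=atom_index,
        normals=normals,
    )


def write_msms(mesh: TriMesh3D, vert_path: str, face_path: str) -> None:
    """Write a mesh as an MSMS-style .vert/.face pair (0-based indices
    converted back to 1-based)."""
    normals = mesh.vertex_normals()
    atom = (
        mesh.atom_index
        if mesh.atom_index is not None
        else np.ones(mesh.n_vertices, dtype=np.int64)
    )
    with open(vert_path, "w") as fh:
        fh.write("# written by surfcart\n")
        fh.write(f"{mesh.n_vertices} 0 0.0 0.0\n")
        for v, nrm, a in zip(mesh.vertices, normals, atom):
            fh.write(
                f"{v[0]:9.3f} {v[1]:9.3f} {v[2]:9.3f} "
                f"{nrm[0]:9.3f} {nrm[1]:9.3f} {nrm[2]:9.3f} 0 {a:d} 1\n"
            )
    with open(face_path, "w") as fh:
        fh.write("# written by surfcart\n")
        fh.write(f"{mesh.n_faces} 0\n")
        for f in mesh.faces:
            fh.write(f"{f[0] + 1:7d} {f[1] + 1:7d} {f[2] + 1:7d} 1 1\n")


# ----------------------------------------------------------------- PDB

@dataclass
class Atom:
    element: str
    name: str
    resname: str
    resnum: int
    chain: str
    coord: np.ndarray
    charge: Optional[float] = None
    is_hetatm: bool = False


@dataclass
class Structure:
    """Flat atom list parsed from a PDB file (first model, one altloc)."""

    atoms: List[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise FormatError("structure contains no atoms")

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    def residues(self):
        """Group atoms into residues, ordered by first appearance.

        Yields ((chain, resnum, resname), [atoms]) tuples.
        """
        groups: dict = {}
        for a in self.atoms:
            groups.setdefault((a.chain, a.resnum, a.resname), []).append(a)
        return list(groups.items())


def read_pdb(
    path: str, model: Optional[int] = None, include_hetatm: bool = False
) -> Structure:
    """Parse a fixed-column PDB file into a flat atom list.

    Keeps the first model only (or the given 0-based model index) and,
    for disordered atoms, the highest-occupancy altloc. HETATM records
    (waters, ligands) are excluded unless requested, since they would
    distort surface-property calculations.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("s", path)
    models = list(structure)
    if not models:
        raise FormatError(f"no models in {path}")
    m = models[model or 0]

    atoms: List[Atom] = []
    for chain in m:
        for res in chain:
            het_flag = res.id[0].strip()
            if het_flag and not include_hetatm:
                continue
            for at in res:
                # Disordered atoms expose their highest-occupancy child.
                if at.is_disordered():
                    at = at.selected_child
                atoms.append(
                    Atom(
                        element=(at.element or "").strip(),
                        name=at.get_name(),
                        resname=res.get_resname().strip(),
                        resnum=res.id[1],
                        chain=chain.id,
                        coord=np.asarray(at.coord, dtype=float),
                        is_hetatm=bool(het_flag),
                    )
                )
    if not atoms:
        raise FormatError(f"no ATOM records parsed from {path}")
    if not np.all(np.isfinite(np.array([a.coord for a in atoms]))):
        raise FormatError("non-finite atom coordinates")
    return Structure(atoms=atoms)


# ----------------------------------------------------------------- PLY

def write_ply(
    mesh: TriMesh3D, path: str, vertex_colors: Optional[np.ndarray] = None
) -> None:
    """Write an ASCII PLY, with uchar RGB per vertex when colors given."""
    if vertex_colors is not None:
        vertex_colors = np.asarray(vertex_colors)
        if len(vertex_colors) != mesh.n_vertices:
            raise ArgumentError("vertex_colors length must match vertex count")
        vertex_colors = np.clip(vertex_colors, 0, 255).astype(np.uint8)
        if vertex_colors.ndim != 2 or vertex_colors.shape[1] != 3:
            raise ArgumentError("vertex_colors must be (n, 3) RGB")

    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if vertex_colors is not None:
            fh.write(
                "property uchar red\nproperty uchar green\nproperty uchar blue\n"
            )
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for i, v in enumerate(mesh.vertices):
            line = f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}"
            if vertex_colors is not None:
                c = vertex_colors[i]
                line += f" {c[0]} {c[1]} {c[2]}"
            fh.write(line + "\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_ply(path: str) -> Tuple[TriMesh3D, Optional[np.ndarray]]:
    """Read an ASCII PLY written by :func:`write_ply`.

    Returns (mesh, vertex_colors-or-None).
    """
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise FormatError("not a PLY file")
        n_vert = n_face = 0
        has_color = False
        for line in fh:
            s = line.strip()
            if s.startswith("element vertex"):
                n_vert = int(s.split()[-1])
            elif s.startswith("element face"):
                n_face = int(s.split()[-1])
            elif s.startswith("property uchar red"):
                has_color = True
            elif s == "end_header":
                break
        verts, colors = [], []
        for _ in range(n_vert):
            fields = fh.readline().split()
            verts.append([float(x) for x in fields[:3]])
            if has_color:
                colors.append([int(x) for x in fields[3:6]])
        faces = []
        for _ in range(n_face):
            fields = fh.readline().split()
            if int(fields[0]) != 3:
                raise FormatError("only triangular faces supported")
            faces.append([int(x) for x in fields[1:4]])
    mesh = TriMesh3D(vertices=np.array(verts), faces=np.array(faces, dtype=np.int64))
    return mesh, (np.array(colors, dtype=np.uint8) if has_color else None)


# ----------------------------------------------------------------- PNG

def write_png(image, path: str) -> None:
    """Write a SurfaceImage's 8-bit pixels as a lossless PNG."""
    from PIL import Image

    px = image.pixels
    if px.dtype != np.uint8:
        raise FormatError("only 8-bit channels are supported")
    if px.ndim == 3 and px.shape[2] == 1:
        px = px[:, :, 0]
    Image.fromarray(px).save(path, format="PNG")


def read_png(path: str):
    """Read a PNG back into a SurfaceImage (identity map transform)."""
    from PIL import Image

    from .imaging import MapTransform, SurfaceImage

    with Image.open(path) as im:
        if im.mode not in ("L", "RGB", "RGBA"):
            im = im.convert("RGB")
        arr = np.asarray(im)
    if arr.dtype != np.uint8:
        raise FormatError("only 8-bit PNGs are supported")
    if arr.ndim == 2:
        arr = arr[:, :, None]
    semantics = {1: ("gray",), 3: ("r", "g", "b"), 4: ("r", "g", "b", "a")}[
        arr.shape[2]
    ]
    return SurfaceImage(
        pixels=arr,
        channel_semantics=semantics,
        transform=MapTransform(scale=1.0, x0=0.0, y1=float(arr.shape[0])),
    )


# ----------------------------------------------- residue annotation list

def read_residue_list(path: str) -> List[Tuple[str, int]]:
    """Read a plain-text annotation list, one "chain residue_number"
    pair per line ('#' starts a comment)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.split("#")[0].strip()
            if not s:
                continue
            fields = s.split()
            if len(fields) != 2:
                raise FormatError(
                    f"expected 'chain residue_number' at line {lineno}"
                )
            out.append((fields[0], int(fields[1])))
    return out
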