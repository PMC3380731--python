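import numpy as np
import pytest

import surfcart as sc
from surfcart.features import FORMAL_CHARGES, PotentialGrid
from surfcart.types import ArgumentError

from conftest import make_structure


def _flat_patch(nx=8, ny=8, spacing=1.0):
    """Open planar grid mesh in the z=0 plane, normals +z."""
    xx, yy = np.meshgrid(
        np.arange(nx) * spacing, np.arange(ny) * spacing, indexing="ij"
    )
    v = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            faces.append((v00, v00 + ny, v00 + ny + 1))
            faces.append((v00, v00 + ny + 1, v00 + 1))
    return sc.TriMesh3D(vertices=v, faces=np.array(faces))


class TestHydrophobicity:
    def test_poly_isoleucine_takes_scale_maximum(self, hemisphere):
        # one ILE atom under each vertex: every vertex inherits +4.5,
        # the extreme of the embedded Kyte-Doolittle table
        struct = make_structure(
            [("ILE", 1, [("CA", hemisphere.vertices[0] * 0.9)])]
        )
        field = sc.kd_hydrophobicity(struct, hemisphere, cutoff=10.0)
        assert np.all(field.values == 4.5)
        assert max(sc.KYTE_DOOLITTLE.values()) == 4.5

    def test_values_come_from_embedded_scale(self, hemisphere):
        rng = np.random.default_rng(3)
        names = list(sc.KYTE_DOOLITTLE)
        residues = [
            (names[rng.integers(len(names))], i + 1, [("CA", v)])
            for i, v in enumerate(hemisphere.vertices[::7])
        ]
        struct = make_structure(residues)
        field = sc.kd_hydrophobicity(struct, hemisphere, cutoff=10.0)
        allowed = set(sc.KYTE_DOOLITTLE.values())
        assert set(np.unique(field.values)) <= allowed

    def test_unknown_residue_rejected(self, tri_mesh):
        struct = make_structure([("XYZ", 1, [("CA", [0.3, 0.3, 0.0])])])
        with pytest.raises(ArgumentError, match="XYZ"):
            sc.kd_hydrophobicity(struct, tri_mesh)

    def test_no_atom_within_cutoff_rejected(self, tri_mesh):
        struct = make_structure([("GLY", 1, [("CA", [50.0, 0, 0])])])
        with pytest.raises(ArgumentError, match="vertex"):
            sc.kd_hydrophobicity(struct, tri_mesh, cutoff=5.0)

    def test_msms_atom_index_used_when_present(self):
        mesh = sc.TriMesh3D(
            vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
            faces=np.array([[0, 1, 2]]),
            atom_index=np.array([1, 2, 2]),
        )
        struct = make_structure(
            [("ILE", 1, [("CA", [9, 9, 9])]), ("ARG", 2, [("CA", [9, 9, 9])])]
        )
        field = sc.kd_hydrophobicity(struct, mesh)
        assert list(field.values) == [4.5, -4.5, -4.5]


class TestCoulombPotential:
    def test_no_charges_gives_zero_field(self, tri_mesh):
        struct = make_structure([("GLY", 1, [("CA", [0.3, 0.3, 0.0])])])
        field = sc.coulomb_potential(struct, tri_mesh)
        assert np.all(field.values == 0.0)

    def test_single_unit_charge_at_two_angstroms(self):
        mesh = sc.TriMesh3D(
            vertices=np.array([[2.0, 0, 0], [0, 2, 0], [0, 0, 2]]),
            faces=np.array([[0, 1, 2]]),
        )
        struct = make_structure([("GLY", 1, [("CA", [0.0, 0, 0])])])
        field = sc.coulomb_potential(
            struct, mesh, charges=[(np.zeros(3), 1.0)]
        )
        # phi = q / (eps(d) * d) = 1 / (4*2 * 2) = 1/16
        assert np.allclose(field.values, 1.0 / 16.0)

    def test_antisymmetric_for_mirror_charge_pair(self):
        z = np.linspace(-3, 3, 13)
        mesh = sc.TriMesh3D(
            vertices=np.column_stack([np.full(13, 5.0), np.zeros(13), z]),
            faces=np.array([[0, 1, 2]]),
        )
        struct = make_structure([("GLY", 1, [("CA", [5.0, 0, 10.0])])])
        charges = [
            (np.array([0.0, 0, 2.0]), 1.0),
            (np.array([0.0, 0, -2.0]), -1.0),
        ]
        field = sc.coulomb_potential(struct, mesh, charges=charges)
        assert np.allclose(field.values, -field.values[::-1], atol=1e-9)

    def test_default_charge_assignment(self):
        struct = make_structure(
            [
                ("ASP", 1, [("N", [0, 0, 0]), ("CG", [1, 0, 0])]),
                ("LYS", 2, [("NZ", [5, 0, 0]), ("C", [6, 0, 0])]),
            ]
        )
        charges = sc.features.assign_formal_charges(struct)
        q_by_pos = {tuple(p): q for p, q in charges}
        assert q_by_pos[(1.0, 0.0, 0.0)] == -1.0  # Asp side chain
        assert q_by_pos[(5.0, 0.0, 0.0)] == 1.0  # Lys side chain
        assert q_by_pos[(0.0, 0.0, 0.0)] == 1.0  # N-terminus
        assert q_by_pos[(6.0, 0.0, 0.0)] == -1.0  # C-terminus
        assert set(FORMAL_CHARGES) == {"ASP", "GLU", "LYS", "ARG", "HIS"}


DX_TEMPLATE = """\
# synthetic OpenDX scalar grid
object 1 class gridpositions counts {nx} {ny} {nz}
origin 0.0 0.0 0.0
delta 1.0 0.0 0.0
delta 0.0 1.0 0.0
delta 0.0 0.0 1.0
object 2 class gridconnections counts {nx} {ny} {nz}
object 3 class array type double rank 0 items {n} data follows
{data}
"""


def _write_dx(tmp_path, values, shape=(3, 3, 3)):
    data = "\n".join(
        " ".join(f"{v:.6f}" for v in values[i : i + 3])
        for i in range(0, len(values), 3)
    )
    path = tmp_path / "grid.dx"
    path.write_text(
        DX_TEMPLATE.format(
            nx=shape[0], ny=shape[1], nz=shape[2], n=len(values), data=data
        )
    )
    return str(path)


class TestPotentialGrid:
    def test_constant_grid_constant_field(self, tmp_path, tri_mesh):
        path = _write_dx(tmp_path, [2.5] * 27)
        grid = sc.load_potential_grid(path)
        field = sc.sample_potential(grid, tri_mesh)
        assert np.allclose(field.values, 2.5)

    def test_linear_ramp_reproduced_exactly(self, tmp_path):
        # f(x,y,z) = x: trilinear interpolation is exact on linear fields
        xs = np.repeat(np.arange(3.0), 9)
        path = _write_dx(tmp_path, list(xs))
        grid = sc.load_potential_grid(path)
        mesh = sc.TriMesh3D(
            vertices=np.array([[0.25, 1, 1], [1.75, 0.5, 0.5], [1.0, 2.0, 0.1]]),
            faces=np.array([[0, 1, 2]]),
        )
        field = sc.sample_potential(grid, mesh)
        assert np.allclose(field.values, mesh.vertices[:, 0], atol=1e-12)

    def test_outside_vertex_clamped_with_warning(self, tmp_path):
        path = _write_dx(tmp_path, [1.0] * 27)
        grid = sc.load_potential_grid(path)
        mesh = sc.TriMesh3D(
            vertices=np.array([[10.0, 1, 1], [1, 1, 1], [0.5, 1, 1]]),
            faces=np.array([[0, 1, 2]]),
        )
        with pytest.warns(UserWarning, match="1 vertices outside"):
            field = sc.sample_potential(grid, mesh)
        assert np.allclose(field.values, 1.0)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.dx"
        path.write_text("origin 0 0 0\n1.0 2.0\n")
        with pytest.raises(sc.FormatError):
            sc.load_potential_grid(str(path))


class TestMeanCurvature:
    def test_unit_sphere_curvature_is_one(self):
        mesh = sc.make_icosphere(3)
        h = sc.mean_curvature(mesh)
        assert np.all(np.abs(h.values - 1.0) <= 0.1)

    def test_radius_scaling_halves_curvature(self):
        base = sc.make_icosphere(3)
        big = sc.TriMesh3D(vertices=2.0 * base.vertices, faces=base.faces)
        h1 = sc.mean_curvature(base)
        h2 = sc.mean_curvature(big)
        assert np.allclose(h2.values, 0.5 * h1.values, atol=0.05)

    def test_planar_interior_is_flat(self):
        mesh = _flat_patch()
        h = sc.mean_curvature(mesh)
        # interior vertices of a plane have zero mean curvature
        interior = (
            (mesh.vertices[:, 0] > 0.5)
            & (mesh.vertices[:, 0] < 6.5)
            & (mesh.vertices[:, 1] > 0.5)
            & (mesh.vertices[:, 1] < 6.5)
        )
        assert np.all(np.abs(h.values[interior]) < 1e-6)

    def test_saddle_patch_has_mixed_signs(self):
        flat = _flat_patch(nx=10, ny=10, spacing=0.4)
        x = flat.vertices[:, 0] - 1.8
        y = flat.vertices[:, 1] - 1.8
        saddle = sc.TriMesh3D(
            vertices=np.column_stack([x, y, 0.5 * (x**2 - y**2)]),
            faces=flat.faces,
        )
        h = sc.mean_curvature(saddle)
        assert (h.values > 1e-3).any() and (h.values < -1e-3).any()

    def test_inconsistent_orientation_rejected(self):
        mesh = sc.TriMesh3D(
            vertices=np.array(
                [[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.2]]
            ),
            faces=np.array([[0, 1, 2], [1, 3, 2]]),
        )
        flipped = sc.TriMesh3D(
            vertices=mesh.vertices, faces=np.array([[0, 1, 2], [1, 2, 3]])
        )
        sc.mean_curvature(mesh)  # consistent: fine
        with pytest.raises(ArgumentError, match="orientation"):
            sc.mean_curvature(flipped)

    def test_rigid_motion_invariance(self):
        mesh = sc.make_icosphere(2)
        th = 0.9
        rot = np.array(
            [
                [np.cos(th), -np.sin(th), 0],
                [np.sin(th), np.cos(th), 0],
                [0, 0, 1],
            ]
        )
        moved = sc.TriMesh3D(
            vertices=mesh.vertices @ rot.T + np.array([3.0, -1.0, 2.0]),
            faces=mesh.faces,
        )
        assert np.allclose(
            sc.mean_curvature(mesh).values,
            sc.mean_curvature(moved).values,
            atol=1e-9,
        )


class TestAnnotationMask:
    def _setup(self, hemisphere):
        struct = make_structure(
            [
                ("SER", 1, [("CA", hemisphere.vertices[0])]),
                ("HIS", 2, [("CA", hemisphere.vertices[20])]),
            ]
        )
        return struct

    def test_empty_list_all_zero(self, hemisphere):
        struct = self._setup(hemisphere)
        mask = sc.annotation_mask([], struct, hemisphere, cutoff=10.0)
        assert not mask.values.any()

    def test_full_list_all_one(self, hemisphere):
        struct = self._setup(hemisphere)
        mask = sc.annotation_mask(
            [("A", 1), ("A", 2)], struct, hemisphere, cutoff=10.0
        )
        assert mask.values.all()

    def test_single_residue_matches_nearest_atom_assignment(self, hemisphere):
        struct = self._setup(hemisphere)
        mask = sc.annotation_mask([("A", 2)], struct, hemisphere, cutoff=10.0)
        # brute-force nearest-atom assignment; ignore exact-tie vertices
        # where either atom is a valid nearest neighbor
        coords = struct.coords()
        d = np.linalg.norm(
            hemisphere.vertices[:, None] - coords[None], axis=2
        )
        decided = np.abs(d[:, 0] - d[:, 1]) > 1e-9
        expected = (d.argmin(axis=1) == 1).astype(float)
        assert np.array_equal(mask.values[decided], expected[decided])
        assert decided.sum() > hemisphere.n_vertices / 2

    def test_missing_residue_warns_and_skips(self, hemisphere):
        struct = self._setup(hemisphere)
        with pytest.warns(UserWarning, match="not in structure"):
            mask = sc.annotation_mask(
                [("A", 99)], struct, hemisphere, cutoff=10.0
            )
        assert not mask.values.any()
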