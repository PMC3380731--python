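import numpy as np
import pytest

import surfcart as sc


@pytest.fixture(scope="session")
def icosphere2():
    return sc.make_icosphere(2)


@pytest.fixture(scope="session")
def hemisphere():
    """Reference benchmark hemisphere: icosphere(2) cut at z >= 0."""
    return sc.reference_hemisphere()


@pytest.fixture(scope="session")
def cylinder():
    """Graded developable cylinder sector (the flattening oracle)."""
    return sc.make_cylinder_patch(
        radius=2.0, height=3.0, n_u=20, n_v=20,
        angular_extent=np.pi, graded=True,
    )


@pytest.fixture(scope="session")
def cylinder_development():
    return sc.develop_cylinder_patch(
        radius=2.0, height=3.0, n_u=20, n_v=20,
        angular_extent=np.pi, graded=True,
    )


@pytest.fixture(scope="session")
def planar_grid():
    """Flat, irregularly spaced triangulated grid in the z=0 plane."""
    x = np.array([0.0, 0.7, 1.9, 3.0])
    y = np.array([0.0, 0.9, 2.4, 3.2, 4.0])
    xx, yy = np.meshgrid(x, y, indexing="ij")
    vertices = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    faces = []
    n_v = len(y)
    for i in range(len(x) - 1):
        for j in range(n_v - 1):
            v00 = i * n_v + j
            faces.append((v00, v00 + n_v, v00 + n_v + 1))
            faces.append((v00, v00 + n_v + 1, v00 + 1))
    return sc.TriMesh3D(vertices=vertices, faces=np.array(faces))


def make_structure(residues):
    """Build a synthetic Structure from (resname, resnum, [(atom, xyz)]).

    All atoms on chain A; element guessed from the first letter of the
    atom name.
    """
    atoms = []
    for resname, resnum, atom_list in residues:
        for name, xyz in atom_list:
            atoms.append(
                sc.Atom(
                    element=name[0],
                    name=name,
                    resname=resname,
                    resnum=resnum,
                    chain="A",
                    coord=np.asarray(xyz, dtype=float),
                )
            )
    return sc.Structure(atoms=atoms)


@pytest.fixture()
def tri_mesh():
    """One right triangle with unit legs."""
    return sc.TriMesh3D(
        vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
        faces=np.array([[0, 1, 2]]),
    )
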