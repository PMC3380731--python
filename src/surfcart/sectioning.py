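"""Split an enclosed surface into six coordinate half-sections.

An enclosed surface cannot be flattened without collapsing antipodal
regions onto each other, so the surface is bisected by the three
coordinate planes into six open half-sections (+x, -x, +y, -y, +z,
-z), each of which can be mapped on its own.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional

import numpy as np

from .synthetic_surfaces import cut_halfspace
from .types import EmptySectionError, TriMesh3D

SECTION_LABELS = ("+x", "-x", "+y", "-y", "+z", "-z")


def bisect_by_planes(
    mesh: TriMesh3D, origin: Optional[np.ndarray] = None
) -> Dict[str, TriMesh3D]:
    """Cut a mesh by the three axis-aligned planes through ``origin``.

    Returns the six half-sections keyed ``+x, -x, +y, -y, +z, -z``.
    ``origin`` defaults to the vertex centroid (translation-invariant);
    pass ``(0, 0, 0)`` to cut at the raw coordinate planes instead.
    Opposing sections share the vertices lying exactly on the plane;
    faces straddling a plane belong to neither of its two sections.
    An empty section raises a warning and is returned as a zero-face
    mesh.
    """
    if origin is None:
        origin = mesh.centroid()
    sections: Dict[str, TriMesh3D] = {}
    for label in SECTION_LABELS:
        sign, axis = label[0], label[1]
        try:
            section, _ = cut_halfspace(mesh, axis, sign, origin)
        except EmptySectionError:
            warnings.warn(f"section {label} is empty", stacklevel=2)
            section = TriMesh3D(
                vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=np.int64)
            )
        sections[label] = section
    return sections


def reference_hemisphere(level: int = 2) -> TriMesh3D:
    """The benchmark hemisphere: a level-``level`` icosphere cut at the
    z >= 0 half-space through its center."""
    from .synthetic_surfaces import make_icosphere

    sphere = make_icosphere(level)
    hemi, _ = cut_halfspace(sphere, "z", "+", origin=np.zeros(3))
    return hemi
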