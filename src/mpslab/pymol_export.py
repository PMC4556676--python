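"""Static PyMOL export of the implicit membrane as two parallel planes.

The planes sit at ``center ± (T/2) · normal``, each perpendicular to the
membrane normal, drawn as compiled graphics objects (CGO quads).
"""

from __future__ import annotations

import numpy as np

from .core import MembraneGeometry

__all__ = ["membrane_plane_vertices", "write_pymol_planes"]


def membrane_plane_vertices(geom: MembraneGeometry, half_width: float = 40.0):
    """Corner vertices of the two membrane boundary planes.

    Returns a list of two (4, 3) arrays, one per leaflet plane.
    """
    n = geom.normal
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, n)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    planes = []
    for sign in (1.0, -1.0):
        c = geom.center + sign * geom.half_thickness * n
        planes.append(np.array([
            c + half_width * (u + v),
            c + half_width * (u - v),
            c - half_width * (u + v),
            c - half_width * (u - v),
        ]))
    return planes


def write_pymol_planes(geom: MembraneGeometry, half_width: float = 40.0,
                       name: str = "membrane") -> str:
    """PyMOL-loadable script drawing the two membrane planes as CGO quads."""
    planes = membrane_plane_vertices(geom, half_width)
    lines = [
        "from pymol.cgo import BEGIN, QUADS, VERTEX, COLOR, ALPHA, END",
        "from pymol import cmd",
        "obj = [BEGIN, QUADS, COLOR, 0.5, 0.6, 0.8, ALPHA, 0.5]",
    ]
    for plane in planes:
        for vert in plane:
            lines.append(f"obj += [VERTEX, {vert[0]:.3f}, {vert[1]:.3f}, {vert[2]:.3f}]")
    lines += [
        "obj += [END]",
        f"cmd.load_cgo(obj, {name!r})",
    ]
    return "\n".join(lines) + "\n"
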