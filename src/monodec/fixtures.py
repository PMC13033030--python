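"""Deterministic mesh fixtures: regular hexagonal patches and annuli.

These meshes have edges exactly orthogonal to links, which makes them the
reference configuration for the operator degeneracies that hold only in
the orthogonal case (``L_V = L_T``, ``grad^v = -corot^v``, ...).  Applying
a shear breaks orthogonality and those degeneracies, which is equally
useful in tests.
"""

from __future__ import annotations

import numpy as np

from .mesh import MonolayerTopology, build_topology

__all__ = [
    "hexagonal_patch",
    "fixture_hexagonal_patch",
    "fixture_annulus",
    "shear_positions",
]

_CORNERS = None


def _hex_corners(side: float) -> np.ndarray:
    # pointy-top hexagon corners, clockwise winding (negative shoelace)
    ang = np.pi / 6 - np.arange(6) * np.pi / 3
    return side * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def hexagonal_patch(rings: int, side: float = 1.0):
    """Centred hexagonal patch with ``3 rings (rings+1) + 1`` unit cells.

    Returns ``(cells, positions)`` where cells are positive-shoelace vertex
    cycles.  ``rings=0`` is a single hexagon.
    """
    if rings < 0:
        raise ValueError("rings must be >= 0")
    corners = _hex_corners(side)
    # axial coordinates of cell centres
    centres = []
    for q in range(-rings, rings + 1):
        for s in range(max(-rings, -q - rings), min(rings, -q + rings) + 1):
            centres.append((q, s))
    ax = np.array([[np.sqrt(3.0), np.sqrt(3.0) / 2.0], [0.0, 1.5]]) * side
    vert_index: dict[tuple[int, int], int] = {}
    positions: list[np.ndarray] = []
    cells: list[list[int]] = []
    scale = 1.0 / (side * 1e-6)
    for q, s in centres:
        centre = ax @ np.array([q, s], dtype=float)
        cyc = []
        for corner in corners:
            p = centre + corner
            key = (int(round(p[0] * scale)), int(round(p[1] * scale)))
            if key not in vert_index:
                vert_index[key] = len(positions)
                positions.append(p)
            cyc.append(vert_index[key])
        cells.append(cyc)
    return cells, np.asarray(positions)


def fixture_hexagonal_patch(rings: int, side: float = 1.0
                            ) -> tuple[MonolayerTopology, np.ndarray]:
    """Topology + positions for a regular hexagonal patch."""
    cells, r = hexagonal_patch(rings, side)
    return build_topology(cells), r


def fixture_annulus(rings: int, holes: int = 1, side: float = 1.0
                    ) -> tuple[MonolayerTopology, np.ndarray]:
    """Hexagonal patch with 1 or 2 interior cells removed (vertices kept).

    ``rings >= 2`` so the removed cells never touch the outer periphery.
    With one hole the central cell is removed; with two, a pair of cells
    placed symmetrically about the centre and separated by at least one
    intact cell.
    """
    if rings < 2:
        raise ValueError("need rings >= 2 so removals avoid the periphery")
    if holes not in (1, 2):
        raise ValueError("holes must be 1 or 2")
    cells, r = hexagonal_patch(rings, side)
    centres = np.array([r[c].mean(axis=0) for c in cells])
    order = np.argsort(np.linalg.norm(centres, axis=1))
    if holes == 1:
        drop = {int(order[0])}
    else:
        # two cells on opposite sides of the centre, two rows apart
        target = np.array([np.sqrt(3.0) * side, 0.0])
        i1 = int(np.argmin(np.linalg.norm(centres - target, axis=1)))
        i2 = int(np.argmin(np.linalg.norm(centres + target, axis=1)))
        if i1 == i2:
            raise ValueError("could not select two distinct cells")
        drop = {i1, i2}
    kept = [c for i, c in enumerate(cells) if i not in drop]
    used = sorted({v for c in kept for v in c})
    remap = {v: i for i, v in enumerate(used)}
    kept = [[remap[v] for v in c] for c in kept]
    return build_topology(kept), r[used]


def shear_positions(r: np.ndarray, shear: float = 0.3) -> np.ndarray:
    """Affine map ``x -> x + shear * y`` breaking edge-link orthogonality."""
    out = np.asarray(r, dtype=float).copy()
    out[:, 0] += shear * out[:, 1]
    return out
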