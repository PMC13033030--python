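"""JSON serialization for meshes, cochains and simulation states.

The mesh format is a plain JSON object::

    {"vertices": [[x, y], ...],
     "cells": [[v0, v1, ...], ...],
     "orientation": "clockwise",
     "index_base": 0,
     "metadata": {...}}

Vertex indices are 0-based; cells are wound clockwise (negative shoelace).
The reader validates winding and confluence; the writer is bit-stable
(``repr``-round-trip floats, sorted keys).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .dec import Cochain
from .mesh import OrientationError
from .monolayer import Monolayer
from .vertex_model import SimulationState

__all__ = [
    "mesh_to_dict",
    "mesh_from_dict",
    "save_mesh",
    "load_mesh",
    "cochain_to_dict",
    "cochain_from_dict",
    "save_state",
    "load_state",
]


def _dump(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1))


def mesh_to_dict(mono: Monolayer, metadata: dict | None = None) -> dict:
    return {
        "vertices": [[float(x), float(y)] for x, y in mono.r],
        "cells": [[int(v) for v in cyc] for cyc in mono.topology.cells],
        "orientation": "clockwise",
        "index_base": 0,
        "metadata": metadata or {},
    }


def mesh_from_dict(data: dict) -> Monolayer:
    base = int(data.get("index_base", 0))
    cells = [[int(v) - base for v in cyc] for cyc in data["cells"]]
    r = np.asarray(data["vertices"], dtype=float)
    if data.get("orientation", "clockwise") != "clockwise":
        raise OrientationError("mesh file must declare clockwise orientation")
    mono = Monolayer(cells, r)
    mono.geometry  # validates winding (positive areas), confluence
    return mono


def save_mesh(mono: Monolayer, path, metadata: dict | None = None) -> None:
    _dump(mesh_to_dict(mono, metadata), path)


def load_mesh(path) -> Monolayer:
    return mesh_from_dict(json.loads(Path(path).read_text()))


def cochain_to_dict(cochain: Cochain, name: str = "field") -> dict:
    return {
        "name": name,
        "network": cochain.network,
        "degree": int(cochain.degree),
        "rank": int(cochain.rank),
        "values": np.asarray(cochain.values).tolist(),
    }


def cochain_from_dict(data: dict) -> Cochain:
    return Cochain(data["network"], int(data["degree"]),
                   np.asarray(data["values"], dtype=float),
                   int(data["rank"]))


def save_state(state: SimulationState, path) -> None:
    obj = {
        "cells": [[int(v) for v in c] for c in state.cells],
        "vertices": [[float(x), float(y)] for x, y in state.r],
        "time": float(state.time),
        "events": [list(e) for e in state.events],
        "orientation": "clockwise",
        "index_base": 0,
    }
    _dump(obj, path)


def load_state(path) -> SimulationState:
    data = json.loads(Path(path).read_text())
    events = [tuple(e) for e in data.get("events", [])]
    return SimulationState(
        cells=[[int(v) for v in c] for c in data["cells"]],
        r=np.asarray(data["vertices"], dtype=float),
        time=float(data.get("time", 0.0)),
        events=events,
    )
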