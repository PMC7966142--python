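"""Configuration, mesh/field export and tabular output.

Config files are YAML or JSON (all lengths in meters).  Field snapshots
and masks go out as legacy-VTK ASCII structured-points files; surfaces as
STL through trimesh; tables as CSV.  Log lines use structured key=value
formatting so runs can be grepped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import trimesh
import yaml

from .flow import FlowField
from .geometry import DomainGeometry

logger = logging.getLogger("coilpd.io")


def load_config_dict(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def save_config_dict(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True))


def config_hash(cfg: dict) -> str:
    """Stable short hash of a canonicalized config mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def log_kv(event: str, **kw) -> None:
    pairs = " ".join(f"{k}={v}" for k, v in kw.items())
    logger.info("%s %s", event, pairs)


# ---------------------------------------------------------------------------
# VTK / STL export
# ---------------------------------------------------------------------------

def _patch_label_array(geom: DomainGeometry) -> np.ndarray:
    """Integer cell labels: 0 solid, 1 fluid, +10 inlet, +20 outlet, +30 coil."""
    lab = geom.fluid.astype(np.int32).copy()
    codes = {"inlet": 10, "outlet": 20, "coil_plane": 30}
    for name, code in codes.items():
        faces = geom.patches.get(name)
        if faces is not None and faces.shape[0]:
            lab[faces[:, 0], faces[:, 1]] = 1 + code
    return lab


def write_vtk(path: str | Path, geom: DomainGeometry, field: FlowField | None = None) -> None:
    """Legacy-VTK ASCII structured-points file with cell-centered data."""
    nx, ny = geom.fluid.shape
    h = geom.spacing
    x0, y0 = geom.origin
    lines = [
        "# vtk DataFile Version 3.0",
        "coilpd structured fields",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} 2",
        f"ORIGIN {x0:.9g} {y0:.9g} 0",
        f"SPACING {h:.9g} {h:.9g} {h:.9g}",
        f"CELL_DATA {nx * ny}",
    ]

    def scalars(name: str, arr: np.ndarray, kind: str = "float") -> None:
        lines.append(f"SCALARS {name} {kind} 1")
        lines.append("LOOKUP_TABLE default")
        flat = np.ravel(arr, order="F")
        fmt = (lambda v: str(int(v))) if kind == "int" else (lambda v: f"{v:.9g}")
        for start in range(0, flat.size, 9):
            lines.append(" ".join(fmt(v) for v in flat[start : start + 9]))

    scalars("patch_label", _patch_label_array(geom), kind="int")
    if field is not None:
        uc, vc = field.cell_velocity()
        scalars("pressure", np.where(geom.fluid, field.p, 0.0))
        scalars("velocity_x", np.where(geom.fluid, uc, 0.0))
        scalars("velocity_y", np.where(geom.fluid, vc, 0.0))
    Path(path).write_text("\n".join(lines) + "\n")


def write_stl(path: str | Path, geom: DomainGeometry) -> None:
    """Boundary surface extruded one cell in z, written via trimesh."""
    h = geom.spacing
    x0, y0 = geom.origin
    fluid = geom.fluid
    nx, ny = fluid.shape
    verts: list[tuple[float, float, float]] = []
    tris: list[tuple[int, int, int]] = []

    def add_quad(p1, p2):
        base = len(verts)
        verts.extend([(p1[0], p1[1], 0.0), (p2[0], p2[1], 0.0),
                      (p2[0], p2[1], h), (p1[0], p1[1], h)])
        tris.append((base, base + 1, base + 2))
        tris.append((base, base + 2, base + 3))

    faces = np.concatenate([geom.patches[n] for n in ("wall", "inlet", "outlet")
                            if geom.patches[n].shape[0]])
    for i, j, di, dj in faces:
        cx = x0 + (i + 0.5) * h
        cy = y0 + (j + 0.5) * h
        if dj == 0:  # vertical edge at x = cx + di*h/2
            ex = cx + di * h / 2.0
            add_quad((ex, cy - h / 2.0), (ex, cy + h / 2.0))
        else:  # horizontal edge at y = cy + dj*h/2
            ey = cy + dj * h / 2.0
            add_quad((cx - h / 2.0, ey), (cx + h / 2.0, ey))

    mesh = trimesh.Trimesh(vertices=np.asarray(verts), faces=np.asarray(tris), process=False)
    mesh.export(str(path))


def write_summary_csv(path: str | Path, rows: list[Mapping], float_format: str = "%.12g") -> None:
    """Deterministic CSV append-style table of hemodynamic summaries."""
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False, float_format=float_format)
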