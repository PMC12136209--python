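"""File I/O: legacy-ASCII VTK unstructured grids, STL/PLY surfaces, YAML/CSV.

VTK output uses the plain-text legacy format (readable by ParaView and VTK
without any extra dependency); surfaces go through trimesh for STL/PLY.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import yaml

from .mesh import HexMesh
from .surfaces import StructuredSurface
from .synthetic import PatientCase

__all__ = [
    "write_vtk_unstructured",
    "read_vtk_unstructured",
    "surface_to_vtk",
    "hexmesh_to_vtk",
    "write_surface_stl",
    "write_case",
    "load_case_metadata",
]

_VTK_QUAD = 9
_VTK_HEX = 12


def write_vtk_unstructured(
    path: str | os.PathLike,
    points: np.ndarray,
    cells: np.ndarray,
    cell_type: int,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "aortastress",
) -> None:
    """Write points + homogeneous cells as a legacy-ASCII VTK unstructured grid.

    ``cells`` is (n_cells, nodes_per_cell); data arrays may be scalars
    (n,) or vectors/tensors (n, k).
    """
    points = np.asarray(points, float).reshape(-1, 3)
    cells = np.asarray(cells, dtype=int)
    n_cells, npc = cells.shape
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(points)} double",
    ]
    lines += [" ".join(f"{v:.10g}" for v in p) for p in points]
    lines.append(f"CELLS {n_cells} {n_cells * (npc + 1)}")
    lines += [f"{npc} " + " ".join(map(str, c)) for c in cells]
    lines.append(f"CELL_TYPES {n_cells}")
    lines += [str(cell_type)] * n_cells

    def emit(block: dict[str, np.ndarray], n: int, header: str) -> None:
        lines.append(f"{header} {n}")
        for name, arr in block.items():
            arr = np.asarray(arr, float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.10g}" for v in arr)
            else:
                k = arr.shape[1]
                lines.append(f"FIELD {name}_field 1")
                lines.append(f"{name} {k} {arr.shape[0]} double")
                lines.extend(" ".join(f"{v:.10g}" for v in row) for row in arr)

    if point_data:
        emit(point_data, len(points), "POINT_DATA")
    if cell_data:
        emit(cell_data, n_cells, "CELL_DATA")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_unstructured(path: str | os.PathLike):
    """Read back a legacy-ASCII VTK file written by this package.

    Returns (points, cells, point_data, cell_data).  Minimal parser for the
    subset this package writes.
    """
    tokens = Path(path).read_text().split("\n")
    i = 0
    points = cells = None
    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    section = None
    n_section = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = [tokens[i + 1 + j].split() for j in range(n)]
            points = np.array(vals, float)
            i += n
        elif line.startswith("CELLS"):
            n = int(line.split()[1])
            rows = [list(map(int, tokens[i + 1 + j].split()))[1:] for j in range(n)]
            cells = np.array(rows, int)
            i += n
        elif line.startswith("POINT_DATA"):
            section, n_section = point_data, int(line.split()[1])
        elif line.startswith("CELL_DATA"):
            section, n_section = cell_data, int(line.split()[1])
        elif line.startswith("SCALARS") and section is not None:
            name = line.split()[1]
            vals = [float(tokens[i + 2 + j]) for j in range(n_section)]
            section[name] = np.array(vals)
            i += n_section + 1
        elif line.startswith("FIELD") and section is not None:
            i += 1
            name, k, n, _ = tokens[i].split()
            rows = [tokens[i + 1 + j].split() for j in range(int(n))]
            section[name] = np.array(rows, float)
            i += int(n)
        i += 1
    return points, cells, point_data, cell_data


def surface_to_vtk(
    path: str | os.PathLike,
    surface: StructuredSurface,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a structured surface as VTK quads; grid point data is flattened."""
    pd = None
    if point_data:
        pd = {k: np.asarray(v).reshape(len(surface.points()), -1).squeeze() for k, v in point_data.items()}
    write_vtk_unstructured(
        path, surface.points(), surface.quad_connectivity(), _VTK_QUAD, point_data=pd
    )


def hexmesh_to_vtk(
    path: str | os.PathLike,
    mesh: HexMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    base_cell = {"element_set": mesh.elem_set.astype(float)}
    if cell_data:
        base_cell.update(cell_data)
    write_vtk_unstructured(
        path, mesh.nodes, mesh.elems, _VTK_HEX, point_data=point_data, cell_data=base_cell
    )


def write_surface_stl(path: str | os.PathLike, surface: StructuredSurface) -> None:
    """Write a structured surface as an (ASCII) STL or PLY via trimesh."""
    import trimesh

    quads = surface.quad_connectivity()
    tris = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]], axis=0)
    tm = trimesh.Trimesh(vertices=surface.points(), faces=tris, process=False)
    path = Path(path)
    if path.suffix.lower() == ".stl":
        path.write_bytes(trimesh.exchange.stl.export_stl_ascii(tm).encode())
    else:
        tm.export(str(path))


def write_case(case: PatientCase, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write a patient case: surfaces (VTK + STL), YAML metadata sidecar.

    Returns the mapping of artifact names to file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pid = case.patient_id
    paths: dict[str, str] = {}

    base = out / f"patient{pid:02d}_baseline.vtk"
    data = {}
    if case.growth_truth is not None:
        data["growth_truth_pct_per_year"] = case.growth_truth.values.reshape(-1)
    surface_to_vtk(base, case.baseline, point_data=data or None)
    paths["baseline_vtk"] = str(base)

    stl = out / f"patient{pid:02d}_baseline.stl"
    write_surface_stl(stl, case.baseline)
    paths["baseline_stl"] = str(stl)

    if case.followup is not None:
        fu = out / f"patient{pid:02d}_followup.vtk"
        surface_to_vtk(fu, case.followup)
        paths["followup_vtk"] = str(fu)

    meta = {
        "patient_id": pid,
        "systolic_bp_kpa": float(case.systolic_bp_kpa),
        "inlet_flow_l_min": float(case.inlet_flow_l_min),
        "dt_years": None if case.dt_years is None else float(case.dt_years),
        "seed": int(case.params.seed),
        "n_circ": case.baseline.n_circ,
        "n_axial": case.baseline.n_axial,
        "landmark_layers": list(case.baseline.landmark_layers),
        "flap_extent": float(case.params.flap_extent),
        "has_thrombus": bool(case.thrombus_mask.any()),
        "units": {"length": "mm", "pressure": "kPa", "time": "years"},
    }
    ypath = out / f"patient{pid:02d}_meta.yaml"
    ypath.write_text(yaml.safe_dump(meta, sort_keys=False))
    paths["metadata"] = str(ypath)
    return paths


def load_case_metadata(path: str | os.PathLike) -> dict:
    return yaml.safe_load(Path(path).read_text())
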