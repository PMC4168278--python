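"""Plain-text interchange: VTU mesh/field export and YAML run configs.

The VTU writer emits ASCII XML UnstructuredGrid files (VTK cell type 10,
tetrahedron) with nodal point data and per-element cell data — readable by
ParaView and by any VTK-aware library.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional

import numpy as np
import yaml

from .geometry import LabeledTetMesh


def _fmt_array(a: np.ndarray) -> str:
    a = np.asarray(a)
    if np.issubdtype(a.dtype, np.floating):
        return " ".join(f"{v:.9g}" for v in a.ravel())
    return " ".join(str(int(v)) for v in a.ravel())


def _data_arrays(data: Mapping[str, np.ndarray], n: int) -> str:
    chunks = []
    for name, arr in data.items():
        arr = np.asarray(arr)
        if arr.shape[0] != n:
            raise ValueError(f"data array {name!r} has {arr.shape[0]} entries, expected {n}")
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        dtype = "Float64" if np.issubdtype(arr.dtype, np.floating) else "Int32"
        chunks.append(
            f'        <DataArray type="{dtype}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">\n'
            f"          {_fmt_array(arr)}\n        </DataArray>\n"
        )
    return "".join(chunks)


def write_vtu(
    path: str,
    mesh: LabeledTetMesh,
    point_data: Optional[Dict[str, np.ndarray]] = None,
    cell_data: Optional[Dict[str, np.ndarray]] = None,
) -> None:
    """Write the mesh (and optional fields) as an ASCII .vtu file.

    The tissue label is always included as cell data ``region``.
    """
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.region_labels.astype(np.int32))
    point_data = dict(point_data or {})

    n, m = mesh.num_nodes, mesh.num_tets
    offsets = 4 * np.arange(1, m + 1, dtype=np.int64)
    types = np.full(m, 10, dtype=np.int64)  # VTK_TETRA

    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n')
        f.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        f.write("  <UnstructuredGrid>\n")
        f.write(f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n')
        f.write("      <Points>\n")
        f.write('        <DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
        f.write(f"          {_fmt_array(mesh.nodes)}\n")
        f.write("        </DataArray>\n      </Points>\n")
        f.write("      <Cells>\n")
        f.write('        <DataArray type="Int64" Name="connectivity" format="ascii">\n')
        f.write(f"          {_fmt_array(mesh.tets)}\n        </DataArray>\n")
        f.write('        <DataArray type="Int64" Name="offsets" format="ascii">\n')
        f.write(f"          {_fmt_array(offsets)}\n        </DataArray>\n")
        f.write('        <DataArray type="UInt8" Name="types" format="ascii">\n')
        f.write(f"          {_fmt_array(types)}\n        </DataArray>\n")
        f.write("      </Cells>\n")
        f.write("      <PointData>\n")
        f.write(_data_arrays(point_data, n))
        f.write("      </PointData>\n")
        f.write("      <CellData>\n")
        f.write(_data_arrays(cell_data, m))
        f.write("      </CellData>\n")
        f.write("    </Piece>\n  </UnstructuredGrid>\n</VTKFile>\n")


def load_config(path: str) -> dict:
    """Read a YAML experiment configuration."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration file {path!r} must hold a mapping")
    return cfg


def dump_config(cfg: dict, path: str) -> None:
    """Archive a configuration verbatim (sorted keys, deterministic)."""
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)
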