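"""Minimal legacy-ASCII VTK writer for hexahedral results.

Writes an unstructured grid with point vectors (displacement) and cell
scalars (internal fields).  The legacy format is deliberately simple and
readable by ParaView and VisIt.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_vtk"]

_VTK_HEX = 12


def write_vtk(
    path: str | Path,
    nodes: np.ndarray,
    elems: np.ndarray,
    point_vectors: dict[str, np.ndarray] | None = None,
    point_scalars: dict[str, np.ndarray] | None = None,
    cell_scalars: dict[str, np.ndarray] | None = None,
) -> Path:
    path = Path(path)
    n_pts, n_cells = len(nodes), len(elems)
    lines = [
        "# vtk DataFile Version 3.0",
        "tissueheal output",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n_pts} double",
    ]
    lines += [" ".join(f"{x:.10g}" for x in row) for row in nodes]
    lines.append(f"CELLS {n_cells} {9 * n_cells}")
    lines += ["8 " + " ".join(str(i) for i in conn) for conn in elems]
    lines.append(f"CELL_TYPES {n_cells}")
    lines += [str(_VTK_HEX)] * n_cells

    if point_vectors or point_scalars:
        lines.append(f"POINT_DATA {n_pts}")
        for name, arr in (point_vectors or {}).items():
            lines.append(f"VECTORS {name} double")
            lines += [" ".join(f"{x:.10g}" for x in row) for row in arr]
        for name, arr in (point_scalars or {}).items():
            lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
            lines += [f"{x:.10g}" for x in arr]
    if cell_scalars:
        lines.append(f"CELL_DATA {n_cells}")
        for name, arr in cell_scalars.items():
            lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
            lines += [f"{x:.10g}" for x in np.asarray(arr)]
    path.write_text("\n".join(lines) + "\n")
    return path
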