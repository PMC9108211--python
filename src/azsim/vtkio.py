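"""Minimal legacy-ASCII VTK export of voxel fields for visual inspection."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import VoxelGrid

__all__ = ["write_vtk_image"]


def write_vtk_image(path, grid: VoxelGrid, fields: dict[str, np.ndarray],
                    fill: float = np.nan) -> None:
    """Write cell-centered fields as a legacy VTK STRUCTURED_POINTS file.

    ``fields`` maps names to flat fluid-cell vectors (or full 3D arrays);
    obstacle cells are written as ``fill``.
    """
    nx, ny, nz = grid.shape
    lines = [
        "# vtk DataFile Version 3.0",
        "azsim voxel field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        f"ORIGIN {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}",
        f"SPACING {grid.spacing} {grid.spacing} {grid.spacing}",
        f"CELL_DATA {nx * ny * nz}",
    ]
    for name, values in fields.items():
        arr = np.asarray(values, dtype=float)
        if arr.ndim == 1:
            full = grid.to_3d(arr, fill=fill)
        else:
            full = arr
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        # VTK cell ordering: x fastest, then y, then z
        flat = np.transpose(full, (2, 1, 0)).ravel()
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    Path(path).write_text("\n".join(lines) + "\n")
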