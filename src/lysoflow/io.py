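"""Output writers: legacy ASCII VTK point clouds and CSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_vtk_points", "write_flow_vtk"]


def write_vtk_points(
    path: str | Path,
    points: np.ndarray,
    point_data: dict[str, np.ndarray] | None = None,
    title: str = "lysoflow fields",
) -> None:
    """Write a point cloud with per-point scalar/vector data as legacy
    ASCII VTK (readable by ParaView and meshio alike)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines += [" ".join(f"{c:.9e}" for c in p) for p in points]
    lines.append(f"VERTICES {n} {2 * n}")
    lines += [f"1 {i}" for i in range(n)]
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.9e}" for v in arr]
            elif arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{c:.9e}" for c in v) for v in arr]
            else:
                raise ValueError(f"unsupported point data shape {arr.shape}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_flow_vtk(sol, directory: str | Path, stem: str) -> tuple[Path, Path]:
    """Write interior fields and wall shear of a FlowSolution as two VTK
    files; returns their paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    interior = directory / f"{stem}_interior.vtk"
    wall = directory / f"{stem}_wall.vtk"
    write_vtk_points(
        interior,
        sol.mesh_points,
        {"velocity_m_s": sol.velocity_field, "pressure_pa": sol.pressure_field},
        title="lysosomal Stokes flow (interior samples)",
    )
    write_vtk_points(
        wall,
        sol.wall_points,
        {"wall_shear_pa": sol.wall_shear, "traction_pa": sol.wall_traction},
        title="lysosomal wall shear stress",
    )
    return interior, wall
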