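"""Result export, mesh/field writers and plots.

Every exported table is reproducible bit-for-bit from (config, seeds);
wall-clock timestamps appear only in the JSON metadata sidecar, never in the
CSV data files, so re-exports of the same results are idempotent on the data
files.
"""

from __future__ import annotations

import datetime as _dt
import json
import platform
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np

from .meshing import LabeledMesh
from .protocols import ImpedanceMap, SensitivityResult, _jsonable, contact_number
from .validation import ConvergenceReport

__all__ = [
    "export_results",
    "write_msh",
    "write_vtk",
    "write_vtu",
    "plot_depth_profile",
    "plot_proximity_profiles",
    "plot_sensitivity",
]


def _versions() -> Dict[str, str]:
    import scipy

    import scalasim

    return {
        "scalasim": getattr(scalasim, "__version__", "0"),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "python": platform.python_version(),
    }


def _sidecar(payload: Dict, path: Path) -> Path:
    payload = dict(payload)
    payload["versions"] = _versions()
    payload["created_utc"] = _dt.datetime.now(_dt.timezone.utc).isoformat()
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
    return path


def export_results(
    result: Union[ImpedanceMap, SensitivityResult, ConvergenceReport],
    outdir: Union[str, Path],
    basename: Optional[str] = None,
) -> List[Path]:
    """Write a result object as CSV (or JSON) plus a JSON metadata sidecar.

    Returns the list of written paths.  Data files contain no timestamps and
    re-export is idempotent; the sidecar records the config hash, seeds,
    library versions and a creation timestamp.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    if isinstance(result, ImpedanceMap):
        name = basename or str(result.metadata.get("protocol", "impedance_map"))
        csv_path = out / f"{name}.csv"
        result.to_dataframe().to_csv(csv_path, index=False, lineterminator="\n")
        written.append(csv_path)
        written.append(
            _sidecar(
                {
                    "kind": "impedance_map",
                    "n_records": len(result.records),
                    "metadata": result.metadata,
                    "skipped": result.skipped,
                },
                out / f"{name}.meta.json",
            )
        )
    elif isinstance(result, SensitivityResult):
        name = basename or "conductivity_sensitivity"
        csv_path = out / f"{name}.csv"
        result.to_dataframe().to_csv(csv_path, index=False, lineterminator="\n")
        written.append(csv_path)
        written.append(
            _sidecar(
                {
                    "kind": "sensitivity",
                    "layer": result.layer,
                    "contact_id": result.contact_id,
                    "perturbation_factors": result.perturbation_factors,
                    "normalized_deviation": result.normalized_deviation,
                    "normalized_deviation_pct": result.normalized_deviation_pct,
                    "absolute_shift": result.absolute_shift,
                    "metadata": result.metadata,
                },
                out / f"{name}.meta.json",
            )
        )
    elif isinstance(result, ConvergenceReport):
        name = basename or f"convergence_{result.label or 'study'}"
        json_path = out / f"{name}.json"
        json_path.write_text(
            json.dumps(_jsonable(result.to_json_dict()), indent=2, sort_keys=True) + "\n"
        )
        txt_path = out / f"{name}.txt"
        txt_path.write_text(result.to_text() + "\n")
        written.extend([json_path, txt_path])
        written.append(_sidecar({"kind": "convergence"}, out / f"{name}.meta.json"))
    else:
        raise TypeError(f"cannot export {type(result).__name__}")
    return written


# ---------------------------------------------------------------------------
# mesh / field writers


def write_msh(mesh: LabeledMesh, path: Union[str, Path]) -> Path:
    """Write the mesh as Gmsh MSH 2.2 ASCII with physical groups.

    Volume physical ids are ``1 + region code``; surface physical ids are
    ``101 + boundary code`` (offset to keep them disjoint).
    """
    p = Path(path)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines.append("$PhysicalNames")
    lines.append(str(len(mesh.region_names) + len(mesh.boundary_names)))
    for i, name in enumerate(mesh.boundary_names):
        lines.append(f'2 {101 + i} "{name}"')
    for i, name in enumerate(mesh.region_names):
        lines.append(f'3 {1 + i} "{name}"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.16e} {y:.16e} {z:.16e}")
    lines.append("$EndNodes")
    lines.append("$Elements")
    lines.append(str(len(mesh.boundary_tris) + mesh.n_tets))
    eid = 1
    for tri, code in zip(mesh.boundary_tris, mesh.boundary_labels):
        phys = 101 + int(code)
        lines.append(f"{eid} 2 2 {phys} {phys} {tri[0]+1} {tri[1]+1} {tri[2]+1}")
        eid += 1
    for tet, code in zip(mesh.tets, mesh.tet_regions):
        phys = 1 + int(code)
        lines.append(
            f"{eid} 4 2 {phys} {phys} {tet[0]+1} {tet[1]+1} {tet[2]+1} {tet[3]+1}"
        )
        eid += 1
    lines.append("$EndElements")
    p.write_text("\n".join(lines) + "\n")
    return p


def write_vtk(
    mesh: LabeledMesh,
    path: Union[str, Path],
    point_data: Optional[Dict[str, np.ndarray]] = None,
) -> Path:
    """Write the mesh (and optional nodal fields) as legacy ASCII VTK."""
    p = Path(path)
    out = [
        "# vtk DataFile Version 3.0",
        "scalasim mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    out.extend(f"{x:.16e} {y:.16e} {z:.16e}" for x, y, z in mesh.nodes)
    out.append(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}")
    out.extend(f"4 {a} {b} {c} {d}" for a, b, c, d in mesh.tets)
    out.append(f"CELL_TYPES {mesh.n_tets}")
    out.extend(["10"] * mesh.n_tets)
    out.append(f"CELL_DATA {mesh.n_tets}")
    out.append("SCALARS region int 1")
    out.append("LOOKUP_TABLE default")
    out.extend(str(int(r)) for r in mesh.tet_regions)
    if point_data:
        out.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            if values.shape != (mesh.n_nodes,):
                raise ValueError(f"point data {name!r} must have one value per node")
            out.append(f"SCALARS {name} double 1")
            out.append("LOOKUP_TABLE default")
            out.extend(f"{v:.16e}" for v in values)
    p.write_text("\n".join(out) + "\n")
    return p


def write_vtu(
    mesh: LabeledMesh,
    path: Union[str, Path],
    point_data: Optional[Dict[str, np.ndarray]] = None,
) -> Path:
    """Write the mesh (and optional nodal fields) as ASCII XML VTU."""
    p = Path(path)

    def block(arr, fmt):
        return " ".join(fmt % tuple(row) if arr.ndim > 1 else fmt % row for row in arr)

    pieces = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_tets}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        block(mesh.nodes, "%.16e %.16e %.16e"),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        block(mesh.tets, "%d %d %d %d"),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(4 * (i + 1)) for i in range(mesh.n_tets)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(["10"] * mesh.n_tets),
        "</DataArray>",
        "</Cells>",
        "<CellData>",
        '<DataArray type="Int64" Name="region" format="ascii">',
        " ".join(str(int(r)) for r in mesh.tet_regions),
        "</DataArray>",
        "</CellData>",
    ]
    if point_data:
        pieces.append("<PointData>")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            if values.shape != (mesh.n_nodes,):
                raise ValueError(f"point data {name!r} must have one value per node")
            pieces.append(f'<DataArray type="Float64" Name="{name}" format="ascii">')
            pieces.append(" ".join(f"{v:.16e}" for v in values))
            pieces.append("</DataArray>")
        pieces.append("</PointData>")
    pieces.extend(["</Piece>", "</UnstructuredGrid>", "</VTKFile>"])
    p.write_text("\n".join(pieces) + "\n")
    return p


# ---------------------------------------------------------------------------
# plots


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_depth_profile(imap: ImpedanceMap, path: Union[str, Path]) -> Path:
    """Per-contact impedance of a depth profile / final insertion step."""
    plt = _pyplot()
    step = max(r.placement.insertion_step for r in imap.records)
    recs = sorted(
        (r for r in imap.records if r.placement.insertion_step == step),
        key=lambda r: contact_number(r.contact_id),
    )
    x = [contact_number(r.contact_id) for r in recs]
    z = [r.Z_el_ohm / 1e3 for r in recs]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(x, z, "o-")
    ax.set_xlabel("contact (E1 apical ... basal)")
    ax.set_ylabel("impedance (k$\\Omega$)")
    ax.set_title("per-contact impedance, full insertion")
    ax.invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_proximity_profiles(imap: ImpedanceMap, path: Union[str, Path]) -> Path:
    """Impedance vs in-plane offset, one line per recorded contact."""
    plt = _pyplot()
    axis = str(imap.metadata.get("axis", "x"))
    series: Dict[str, List] = {}
    for r in imap.records:
        off = r.placement.x_offset_m if axis == "x" else r.placement.y_offset_m
        series.setdefault(r.contact_id, []).append((off, r.Z_el_ohm))
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for cid in sorted(series, key=contact_number):
        pts = sorted(series[cid])
        ax.plot(
            [p[0] * 1e6 for p in pts],
            [p[1] / 1e3 for p in pts],
            "o-",
            label=cid.replace("CONTACT_", ""),
        )
    ax.set_xlabel(f"{axis} offset from mid-scala ($\\mu$m)")
    ax.set_ylabel("impedance (k$\\Omega$)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_sensitivity(result: SensitivityResult, path: Union[str, Path]) -> Path:
    """Mid-scala-normalized impedance profiles per perturbation factor."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for f in result.perturbation_factors:
        norm = result.normalized_profile(f)
        x = [p[0] * 1e6 for p in result.positions_m]
        ax.plot(x, norm, "o-", label=f"{f:.2f}", markersize=3)
    ax.set_xlabel("x offset from mid-scala ($\\mu$m)")
    ax.set_ylabel("Z / Z(mid-scala)")
    ax.legend(title=f"{result.layer} scale", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
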