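"""Analytic oracles and numerical-verification studies.

The solver is verified against closed-form resistances instead of anatomical
reference data: a 1-D bar, a coaxial resistor (with optional thin layer), the
classical disk-contact spreading resistance ``1/(4 sigma a)`` and the
concentric-spheres resistance ``(1/(4 pi sigma)) (1/a - 1/b)``, plus
h-convergence studies with Richardson extrapolation and re-runs of the
reciprocity/linearity properties on the full cochlea geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .conductivity import ConductivityTable
from .fem import FemSystem, SolverOptions, SourceSpec, compute_impedance, solve_potential
from .geometry import GeometryModel
from .meshing import LabeledMesh, MeshOptions, generate_mesh

__all__ = [
    "ConvergenceReport",
    "disk_spreading_resistance",
    "concentric_spheres_resistance",
    "bar_resistance",
    "coaxial_resistance",
    "run_convergence_study",
    "sphere_shell_mesh",
    "disk_contact_geometry",
    "bar_geometry",
    "disk_contact_study",
    "spheres_study",
    "bar_study",
    "run_oracle_suite",
    "ORACLE_TOLERANCES",
]

#: FEM-vs-oracle relative tolerances asserted in the test suite.
ORACLE_TOLERANCES = {"disk": 0.05, "spheres": 0.02, "bar": 0.01}


# ---------------------------------------------------------------------------
# analytic oracles (pure functions)


def disk_spreading_resistance(sigma: float, a: float) -> float:
    """Spreading resistance of a disk contact on a half-space, 1/(4 sigma a)."""
    if not (sigma > 0 and a > 0):
        raise ValueError("sigma and a must be > 0")
    return 1.0 / (4.0 * sigma * a)


def concentric_spheres_resistance(sigma: float, a: float, b: float) -> float:
    """Resistance between concentric spheres, (1/(4 pi sigma)) (1/a - 1/b)."""
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    if not 0 < a < b:
        raise ValueError("need 0 < a < b")
    return (1.0 / (4.0 * math.pi * sigma)) * (1.0 / a - 1.0 / b)


def bar_resistance(sigma: float, length: float, area: float) -> float:
    """Resistance of a uniform bar, L / (sigma A)."""
    if not (sigma > 0 and length > 0 and area > 0):
        raise ValueError("all arguments must be > 0")
    return length / (sigma * area)


def coaxial_resistance(
    sigma: float,
    r_inner: float,
    r_outer: float,
    length: float,
    layer_areal_resistance: float = 0.0,
    r_layer: Optional[float] = None,
) -> float:
    """Radial resistance of a coaxial resistor, optionally with a thin layer.

    ``ln(r_outer/r_inner) / (2 pi sigma L)`` plus, if
    ``layer_areal_resistance`` (t/sigma_layer, ohm m^2) is given, the series
    contribution of a cylindrical thin layer at radius ``r_layer``.
    """
    if not (sigma > 0 and length > 0):
        raise ValueError("sigma and length must be > 0")
    if not 0 < r_inner < r_outer:
        raise ValueError("need 0 < r_inner < r_outer")
    r = math.log(r_outer / r_inner) / (2.0 * math.pi * sigma * length)
    if layer_areal_resistance:
        if r_layer is None or not r_inner <= r_layer <= r_outer:
            raise ValueError("r_layer must lie between r_inner and r_outer")
        r += layer_areal_resistance / (2.0 * math.pi * r_layer * length)
    return r


# ---------------------------------------------------------------------------
# convergence study


@dataclass
class ConvergenceReport:
    """Impedance of one problem over a decreasing mesh-size sequence."""

    h_m: List[float]
    Z_ohm: List[float]
    Z_star_ohm: Optional[float] = None      # Richardson extrapolation
    observed_order: Optional[float] = None
    oracle_ohm: Optional[float] = None
    rel_errors: List[float] = field(default_factory=list)
    label: str = ""
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.h_m) != len(self.Z_ohm):
            raise ValueError("h_m and Z_ohm must have equal length")
        if any(b >= a for a, b in zip(self.h_m, self.h_m[1:])):
            raise ValueError("h_m must be strictly decreasing")
        if any(e < 0 for e in self.rel_errors):
            raise ValueError("relative errors must be non-negative")

    def to_json_dict(self) -> Dict[str, object]:
        return {
            "label": self.label,
            "h_m": list(self.h_m),
            "Z_ohm": list(self.Z_ohm),
            "Z_star_ohm": self.Z_star_ohm,
            "observed_order": self.observed_order,
            "oracle_ohm": self.oracle_ohm,
            "rel_errors": list(self.rel_errors),
            "metadata": dict(self.metadata),
        }

    def to_text(self) -> str:
        lines = [f"convergence study: {self.label or '(unnamed)'}"]
        header = f"{'h (m)':>12}  {'Z (ohm)':>14}"
        if self.oracle_ohm is not None:
            header += f"  {'rel. error':>10}"
        lines.append(header)
        for i, (h, z) in enumerate(zip(self.h_m, self.Z_ohm)):
            row = f"{h:12.4e}  {z:14.6f}"
            if self.rel_errors:
                row += f"  {self.rel_errors[i]:10.3e}"
            lines.append(row)
        if self.Z_star_ohm is not None:
            lines.append(f"extrapolated Z* = {self.Z_star_ohm:.6f} ohm")
        if self.observed_order is not None:
            lines.append(f"observed order  = {self.observed_order:.2f}")
        if self.oracle_ohm is not None:
            lines.append(f"oracle          = {self.oracle_ohm:.6f} ohm")
        return "\n".join(lines)


def _richardson(h: Sequence[float], z: Sequence[float]) -> Tuple[Optional[float], Optional[float]]:
    """Observed order and extrapolated limit from the last three (h, Z)."""
    if len(h) < 3:
        return None, None
    h1, h2, h3 = h[-3], h[-2], h[-1]
    z1, z2, z3 = z[-3], z[-2], z[-1]
    r12, r23 = h1 / h2, h2 / h3
    d12, d23 = z1 - z2, z2 - z3
    if d23 == 0 or d12 / d23 <= 0:
        return None, z3
    # constant-ratio formula, using the geometric-mean ratio when the two
    # refinement ratios differ slightly
    r = math.sqrt(r12 * r23)
    p = math.log(d12 / d23) / math.log(r)
    z_star = z3 + (z3 - z2) / (r23 ** p - 1.0)
    return p, z_star


def run_convergence_study(
    geom: Union[GeometryModel, Callable[[float], LabeledMesh]],
    cond: ConductivityTable,
    src: SourceSpec,
    h_sequence: Sequence[float],
    oracle_ohm: Optional[float] = None,
    solver_options: Optional[SolverOptions] = None,
    label: str = "",
    far_factor: float = 3.2,
) -> ConvergenceReport:
    """Solve one impedance problem over a decreasing mesh-size sequence.

    ``geom`` is either a :class:`~scalasim.geometry.GeometryModel` (meshed at
    near size ``h`` and far size ``far_factor * h``) or a callable mapping
    ``h`` to a ready :class:`~scalasim.meshing.LabeledMesh`.  Reports the
    Z(h) sequence, Richardson-extrapolated limit and observed order; solver
    failures are re-raised annotated with the offending ``h``.
    """
    hs = [float(h) for h in h_sequence]
    if len(hs) < 3:
        raise ValueError("need at least 3 mesh sizes")
    if any(b >= a for a, b in zip(hs, hs[1:])):
        raise ValueError("h_sequence must be strictly decreasing")
    contact = src.active_contacts[0]
    zs: List[float] = []
    for h in hs:
        try:
            if callable(geom):
                mesh = geom(h)
            else:
                opts = MeshOptions(target_size_near_m=h, target_size_far_m=far_factor * h)
                mesh = generate_mesh(geom, opts)
            fld = solve_potential(mesh, cond, src, solver_options)
            zs.append(compute_impedance(fld, contact, src).Z_el_ohm)
        except Exception as exc:
            raise type(exc)(f"h={h:.4e}: {exc}") from exc
    order, z_star = _richardson(hs, zs)
    errors = [abs(z - oracle_ohm) / abs(oracle_ohm) for z in zs] if oracle_ohm else []
    return ConvergenceReport(
        h_m=hs,
        Z_ohm=zs,
        Z_star_ohm=z_star,
        observed_order=order,
        oracle_ohm=oracle_ohm,
        rel_errors=errors,
        label=label,
        metadata={"contact": contact, "n_meshes": len(hs)},
    )


# ---------------------------------------------------------------------------
# concentric-spheres mesh (cubed-sphere shell)


def _cube_surface_points(n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Deduplicated unit-cube surface grid and per-face quad connectivity.

    Returns ``(points, quads)`` where points lie on the surface of the cube
    ``[-1, 1]^3`` on an ``n x n`` grid per face and quads index into them with
    consistent outward orientation.
    """
    # integer grid coordinates in 0..2n (value = coord * n + n) for exact dedup
    index: Dict[Tuple[int, int, int], int] = {}
    pts: List[Tuple[int, int, int]] = []

    def pid(p: Tuple[int, int, int]) -> int:
        if p not in index:
            index[p] = len(pts)
            pts.append(p)
        return index[p]

    quads: List[Tuple[int, int, int, int]] = []
    # each face: fixed axis k at +-1; u, v the other two axes
    for k in range(3):
        for sign in (+1, -1):
            u, v = (k + 1) % 3, (k + 2) % 3
            for i in range(n):
                for j in range(n):
                    corner_ids = []
                    # counter-clockwise seen from outside for sign=+1
                    steps = [(i, j), (i + 1, j), (i + 1, j + 1), (i, j + 1)]
                    if sign < 0:
                        steps = list(reversed(steps))
                    for (ii, jj) in steps:
                        c = [0, 0, 0]
                        c[k] = sign * n
                        c[u] = 2 * ii - n
                        c[v] = 2 * jj - n
                        corner_ids.append(pid((c[0], c[1], c[2])))
                    quads.append(tuple(corner_ids))
    points = np.array(pts, dtype=float) / n
    return points, np.array(quads, dtype=np.int64)


def sphere_shell_mesh(
    a: float,
    b: float,
    n_surface: int = 8,
    n_radial: int = 8,
    region: str = "scala_tympani",
    contact_label: str = "CONTACT_E1",
    ground_label: str = "GROUND_OUTER",
) -> LabeledMesh:
    """Tetrahedral mesh of the shell between concentric spheres (radii a < b).

    A cubed-sphere grid (``n_surface`` cells per cube-face edge) is projected
    onto the sphere and extruded through ``n_radial`` geometrically spaced
    radial layers; hexahedra are split into 12 tetrahedra about their
    centroid with face diagonals chosen by the smallest global node id, which
    makes the split conforming across all shared faces.  The inner sphere is
    the contact, the outer sphere the ground.
    """
    if not 0 < a < b:
        raise ValueError("need 0 < a < b")
    if n_surface < 2 or n_radial < 1:
        raise ValueError("n_surface >= 2 and n_radial >= 1 required")
    surf, quads = _cube_surface_points(n_surface)
    unit = surf / np.linalg.norm(surf, axis=1, keepdims=True)
    n_pts = len(unit)
    radii = a * (b / a) ** (np.arange(n_radial + 1) / n_radial)
    nodes = (radii[:, None, None] * unit[None, :, :]).reshape(-1, 3)

    n_hex = n_radial * len(quads)
    # hex corner ids: inner quad then outer quad, per radial layer
    q = quads[None, :, :] + (np.arange(n_radial) * n_pts)[:, None, None]
    hexes = np.concatenate([q, q + n_pts], axis=2).reshape(n_hex, 8)

    # centroid nodes
    cent = nodes[hexes].mean(axis=1)
    cent_ids = len(nodes) + np.arange(n_hex)
    nodes = np.vstack([nodes, cent])

    # the six quad faces of a hex with corners (0..3 inner, 4..7 outer),
    # oriented outward from the hex
    faces_local = np.array(
        [
            [3, 2, 1, 0],  # inner (points toward centre)
            [4, 5, 6, 7],  # outer
            [0, 1, 5, 4],
            [1, 2, 6, 5],
            [2, 3, 7, 6],
            [3, 0, 4, 7],
        ]
    )
    tets = []
    for f in faces_local:
        quad = hexes[:, f]  # (n_hex, 4)
        rolls = np.argmin(quad, axis=1)
        # rotate so the global-minimum corner is first; diagonal (0, 2)
        idx = (rolls[:, None] + np.arange(4)[None, :]) % 4
        quad = np.take_along_axis(quad, idx, axis=1)
        tets.append(np.column_stack([quad[:, 0], quad[:, 1], quad[:, 2], cent_ids]))
        tets.append(np.column_stack([quad[:, 0], quad[:, 2], quad[:, 3], cent_ids]))
    tets = np.vstack(tets)

    # fix orientation (positive volume)
    p = nodes[tets]
    vol6 = np.einsum(
        "ij,ij->i", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), p[:, 3] - p[:, 0]
    )
    flip = vol6 < 0
    tets[flip, 0], tets[flip, 1] = tets[flip, 1], tets[flip, 0].copy()
    if np.any(vol6 == 0):
        raise ValueError("degenerate tetrahedra in sphere shell")

    # boundary triangles: inner and outer spherical surfaces, diagonals by the
    # same min-id rule so they match the hex faces
    tris = []
    labels = []
    for layer, code in ((0, 0), (n_radial, 1)):
        quad = quads + layer * n_pts
        rolls = np.argmin(quad, axis=1)
        idx = (rolls[:, None] + np.arange(4)[None, :]) % 4
        quad = np.take_along_axis(quad, idx, axis=1)
        tris.append(np.column_stack([quad[:, 0], quad[:, 1], quad[:, 2]]))
        tris.append(np.column_stack([quad[:, 0], quad[:, 2], quad[:, 3]]))
        labels.extend([code] * (2 * len(quad)))
    boundary_tris = np.vstack(tris)
    boundary_labels = np.array(labels, dtype=np.int64)

    return LabeledMesh(
        nodes=nodes,
        tets=tets.astype(np.int64),
        tet_regions=np.zeros(len(tets), dtype=np.int64),
        region_names=[region],
        boundary_tris=boundary_tris.astype(np.int64),
        boundary_labels=boundary_labels,
        boundary_names=[contact_label, ground_label],
        provenance={
            "kind": "sphere_shell",
            "a_m": repr(a),
            "b_m": repr(b),
            "n_surface": n_surface,
            "n_radial": n_radial,
        },
    )


# ---------------------------------------------------------------------------
# disk-contact verification domain


def disk_contact_geometry(
    a: float,
    domain_factor: float = 40.0,
    region: str = "scala_tympani",
    contact_label: str = "CONTACT_E1",
) -> GeometryModel:
    """Homogeneous cylinder with a disc contact of radius ``a`` on one cap.

    The cap around the disc is insulated (the symmetry plane of the
    half-space problem); the lateral surface and the far cap are grounded at
    distance ``domain_factor * a``, so the FEM value approaches the
    half-space spreading resistance ``1/(4 sigma a)`` from below as the
    domain grows (finite-ground bias of order ``a / domain_factor``).

    The current density is singular at the disc edge, so the radial bands
    are geometrically graded into the edge circle from both sides and the
    axial stations are clustered toward the contact plane; the problem is
    axisymmetric, so a small fixed angular division count loses no accuracy.
    """
    if not a > 0:
        raise ValueError("a must be > 0")
    if domain_factor < 8:
        raise ValueError("domain_factor too small for a half-space surrogate")
    from .geometry import BandSpec, CochleaParams, _ellipse_curve, build_centerline

    R = domain_factor * a
    params = CochleaParams(
        n_turns=0.0,
        length_m=R,
        st_semi_axes_base_m=(R, R),
        st_semi_axes_apex_m=(R, R),
    )
    curves = [
        _ellipse_curve(lambda s: (0.6 * a, 0.6 * a)),
        _ellipse_curve(lambda s: (a, a)),
        _ellipse_curve(lambda s: (R, R)),
    ]
    bands = [
        BandSpec(lambda s, th: region, n_sub=2),
        # graded INTO the edge circle from inside the disc ...
        BandSpec(lambda s, th: region, n_sub=2, grade_inward=True),
        # ... and away from it on the outside
        BandSpec(lambda s, th: region, n_sub=2, grade_outward=True),
    ]
    return GeometryModel(
        centerline=build_centerline(params),
        local_center=lambda s: (0.0, 0.0),
        curves=curves,
        bands=bands,
        surfaces=[],
        outer_label="GROUND_OUTER",
        cap_labels=("INSULATED", "GROUND_OUTER"),
        cap_contact=(0, contact_label, 1),
        forced_stations=(0.0, R),
        refine_span=(0.0, 2.0 * a),
        # cluster stations toward the contact plane (s = 0)
        max_spacing_fn=lambda s: max(0.02 * a, 0.6 * s),
        theta_multiple=8,
        theta_ref_curve=1,
        band_thickness_hint=[0.6 * a, 0.4 * a, R - a],
        provenance={
            "kind": "disk_contact",
            "a_m": repr(a),
            "domain_factor": repr(domain_factor),
        },
        solids={region: "homogeneous half-space surrogate"},
        interfaces={"GROUND_OUTER": "far grounded boundary"},
        params=params,
    )


def bar_geometry(
    length: float = 4e-3,
    semi_axes: Tuple[float, float] = (1e-3, 1e-3),
    region: str = "scala_tympani",
    contact_label: str = "CONTACT_E1",
) -> GeometryModel:
    """Uniform elliptical bar: contact on one cap, ground on the other,
    insulated lateral wall.  Oracle: L / (sigma * pi * a * b)."""
    from .geometry import make_toy_channel

    return make_toy_channel(
        length_m=length,
        semi_axes_base_m=semi_axes,
        block_margin_m=0.0,
        channel_region=region,
        outer_label="INSULATED",
        cap_labels=("INSULATED", "GROUND_OUTER"),
        cap_contact=(0, contact_label),
    )


# ---------------------------------------------------------------------------
# packaged oracle studies (shared by the test suite and the validate CLI)


def bar_study(
    sigma: Optional[float] = None,
    length: float = 4e-3,
    semi_axes: Tuple[float, float] = (1e-3, 1e-3),
    h_sequence: Sequence[float] = (8e-4, 5e-4, 3e-4),
) -> ConvergenceReport:
    """1-D bar resistance study; exact for P1 up to round-off."""
    cond = ConductivityTable()
    sigma = sigma if sigma is not None else cond["scala_tympani"]
    oracle = bar_resistance(sigma, length, math.pi * semi_axes[0] * semi_axes[1])
    geom = bar_geometry(length, semi_axes)
    src = SourceSpec(active_contacts=("CONTACT_E1",))
    return run_convergence_study(geom, cond, src, h_sequence, oracle_ohm=oracle, label="bar")


def spheres_study(
    sigma: Optional[float] = None,
    a: float = 1e-3,
    b: float = 4e-3,
    n_sequence: Sequence[int] = (5, 8, 12),
) -> ConvergenceReport:
    """Concentric-spheres resistance study on cubed-sphere shell meshes."""
    cond = ConductivityTable()
    sigma = sigma if sigma is not None else cond["scala_tympani"]
    oracle = concentric_spheres_resistance(sigma, a, b)
    src = SourceSpec(active_contacts=("CONTACT_E1",))
    ns = sorted(int(n) for n in n_sequence)
    by_h = {(b - a) / n: n for n in ns}

    def factory(h: float) -> LabeledMesh:
        n = by_h[h]
        return sphere_shell_mesh(a, b, n_surface=n, n_radial=n)

    hs = sorted(by_h, reverse=True)
    return run_convergence_study(factory, cond, src, hs, oracle_ohm=oracle, label="spheres")


def disk_contact_study(
    sigma: Optional[float] = None,
    a: float = 5e-4,
    domain_factor: float = 60.0,
    h_sequence: Sequence[float] = (8e-5, 4e-5, 2e-5),
    theta_divisions: int = 16,
) -> ConvergenceReport:
    """Disk spreading-resistance study (axisymmetric-economy meshes)."""
    cond = ConductivityTable()
    sigma = sigma if sigma is not None else cond["scala_tympani"]
    oracle = disk_spreading_resistance(sigma, a)
    geom = disk_contact_geometry(a, domain_factor=domain_factor)
    src = SourceSpec(active_contacts=("CONTACT_E1",))

    def factory(h: float) -> LabeledMesh:
        opts = MeshOptions(
            target_size_near_m=h,
            target_size_far_m=max(1.5e-3, 4 * h),
            theta_divisions=theta_divisions,
        )
        return generate_mesh(geom, opts)

    hs = sorted((float(h) for h in h_sequence), reverse=True)
    return run_convergence_study(factory, cond, src, hs, oracle_ohm=oracle, label="disk")


def run_oracle_suite() -> Dict[str, ConvergenceReport]:
    """Run the three closed-form oracle studies at test-budget sizes.

    Returns reports keyed 'bar', 'spheres', 'disk'; the asserted relative
    tolerances are in :data:`ORACLE_TOLERANCES`.
    """
    reports = {
        "bar": bar_study(),
        "spheres": spheres_study(),
        "disk": disk_contact_study(),
    }
    return reports
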