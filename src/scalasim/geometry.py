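"""Parametric 3D geometry of the implanted scala tympani volume conductor.

The model is a stylized, fully parametric stand-in for an anatomical
(imaging-derived) cochlea: a tapering elliptical duct (the scala tympani)
swept along a conical-helix centerline, bounded by a bony cochlea wall, a
thin highly resistive basilar-membrane layer on the upper side and the
spiral ligament on the lateral side, all embedded in a bone sleeve.  A
16-contact silicone carrier can be placed inside the duct at a configurable
in-plane offset and insertion depth.

Geometry is described as a *ring stack*: a local 2D cross-section made of
nested closed curves (carrier boundary, duct boundary, tissue-layer
boundary, bone boundary) swept along the centerline.  The mesher consumes
this description directly, so region interfaces are meshed exactly (no
voxelization).

Local frame convention: at arc length ``s`` the in-plane axis ``x_hat``
points toward the modiolar (inner) cochlea wall, ``y_hat`` toward the
basilar-membrane side.  Proximity placements are expressed as offsets of
the carrier axis from the duct centerline in this frame.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_simpson

__all__ = [
    "CochleaParams",
    "Centerline",
    "ElectrodeArraySpec",
    "Placement",
    "ProximityGrid",
    "GeometryModel",
    "PlacementInvalid",
    "build_centerline",
    "build_cochlea_geometry",
    "make_proximity_grid",
    "make_toy_channel",
    "ellipse_perimeter",
    "point_to_ellipse_distance",
    "min_curve_clearance",
]

TWO_PI = 2.0 * math.pi

# Angular sectors of the tissue ring around the duct, in turns of the local
# cross-section angle (0 = +x_hat toward the modiolar wall, 0.25 = +y_hat
# toward the basilar membrane).  Edges are multiples of 1/16 so that they
# align with the mesher's angular grid.
MEMBRANE_SECTOR_TURNS = (3.0 / 16.0, 5.0 / 16.0)
LIGAMENT_SECTOR_TURNS = (7.0 / 16.0, 9.0 / 16.0)


class PlacementInvalid(ValueError):
    """Raised when the electrode carrier touches or crosses a bounding layer."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CochleaParams:
    """Dimensions of the parametric cochlea (SI meters).

    The duct cross-section is an ellipse with semi-axes linearly tapering
    (in arc length) from ``st_semi_axes_base_m`` to ``st_semi_axes_apex_m``.
    The centerline is a conical helix whose radius shrinks linearly from
    ``base_radius_m`` to ``apex_radius_m`` over ``n_turns`` turns with an
    axial rise of ``axial_pitch_m`` per turn.  ``n_turns == 0`` degenerates
    to a straight duct of length ``length_m`` (used by test channels).
    """

    n_turns: float = 2.5
    base_radius_m: float = 2.6e-3
    apex_radius_m: float = 1.2e-3
    axial_pitch_m: float = 1.9e-3
    st_semi_axes_base_m: Tuple[float, float] = (0.85e-3, 0.50e-3)
    st_semi_axes_apex_m: Tuple[float, float] = (0.45e-3, 0.28e-3)
    wall_thickness_m: float = 0.15e-3
    membrane_thickness_m: float = 0.04e-3
    ligament_thickness_m: float = 0.15e-3
    bone_margin_m: float = 0.20e-3
    stria_thickness_m: float = 30e-6
    length_m: Optional[float] = None  # straight-duct fallback when n_turns == 0

    def __post_init__(self) -> None:
        lengths = {
            "axial_pitch_m": self.axial_pitch_m,
            "wall_thickness_m": self.wall_thickness_m,
            "membrane_thickness_m": self.membrane_thickness_m,
            "ligament_thickness_m": self.ligament_thickness_m,
            "bone_margin_m": self.bone_margin_m,
            "stria_thickness_m": self.stria_thickness_m,
        }
        if self.n_turns < 0:
            raise ValueError("n_turns must be >= 0")
        if self.n_turns > 0:
            lengths["base_radius_m"] = self.base_radius_m
            lengths["apex_radius_m"] = self.apex_radius_m
            if not self.apex_radius_m < self.base_radius_m:
                raise ValueError("apex_radius_m must be < base_radius_m")
        else:
            if self.length_m is None or not self.length_m > 0:
                raise ValueError(
                    "degenerate spiral: n_turns == 0 requires positive length_m"
                )
        for name, v in lengths.items():
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for pair_name, pair in (
            ("st_semi_axes_base_m", self.st_semi_axes_base_m),
            ("st_semi_axes_apex_m", self.st_semi_axes_apex_m),
        ):
            if len(pair) != 2 or not all(v > 0 for v in pair):
                raise ValueError(f"{pair_name} must be two positive lengths")
        if not (
            self.st_semi_axes_apex_m[0] <= self.st_semi_axes_base_m[0]
            and self.st_semi_axes_apex_m[1] <= self.st_semi_axes_base_m[1]
        ):
            raise ValueError("duct must taper: apex semi-axes <= base semi-axes")

    def lumen_semi_axes(self, s: np.ndarray | float, total_length: float):
        """Duct semi-axes (a, b) at arc length ``s``, linear taper."""
        f = np.clip(np.asarray(s, dtype=float) / total_length, 0.0, 1.0)
        a0, b0 = self.st_semi_axes_base_m
        a1, b1 = self.st_semi_axes_apex_m
        return a0 + (a1 - a0) * f, b0 + (b1 - b0) * f


@dataclass(frozen=True)
class ElectrodeArraySpec:
    """A straight-inserted (lateral wall) array: silicone carrier + contacts.

    Contacts are numbered E1 at the apical tip to ``E{n_contacts}`` at the
    basal end; they are rectangular patches on the carrier surface facing
    the modiolar wall (+x_hat).
    """

    n_contacts: int = 16
    contact_length_m: float = 0.40e-3
    contact_width_m: float = 0.40e-3
    pitch_m: float = 0.85e-3
    carrier_semi_axes_m: Tuple[float, float] = (0.25e-3, 0.25e-3)
    silicone_sigma_S_per_m: float = 1e-7
    tip_margin_m: float = 0.50e-3   # carrier tip to E1 center
    basal_margin_m: float = 0.30e-3  # basal inserted contact edge to duct entry

    def __post_init__(self) -> None:
        if self.n_contacts < 1:
            raise ValueError("n_contacts must be >= 1")
        for name in (
            "contact_length_m",
            "contact_width_m",
            "pitch_m",
            "carrier_semi_axes_m",
            "silicone_sigma_S_per_m",
            "tip_margin_m",
            "basal_margin_m",
        ):
            v = getattr(self, name)
            vals = v if isinstance(v, tuple) else (v,)
            if not all(x > 0 for x in vals):
                raise ValueError(f"{name} must be positive")
        if not self.pitch_m > self.contact_length_m:
            raise ValueError("pitch_m must exceed contact_length_m")

    @property
    def contact_ids(self) -> List[str]:
        return [f"E{i}" for i in range(1, self.n_contacts + 1)]

    def insertion_depth_m(self, insertion_step: int) -> float:
        """Arc-length of the carrier tip from the duct entry when exactly
        ``insertion_step`` contacts are inside the duct."""
        if not 1 <= insertion_step <= self.n_contacts:
            raise ValueError("insertion_step out of range")
        return (
            self.tip_margin_m
            + (insertion_step - 1) * self.pitch_m
            + 0.5 * self.contact_length_m
            + self.basal_margin_m
        )

    def contact_center_s(self, contact_index: int, insertion_step: int) -> float:
        """Arc length of contact E{contact_index} center from the duct entry."""
        depth = self.insertion_depth_m(insertion_step)
        return depth - self.tip_margin_m - (contact_index - 1) * self.pitch_m

    def contact_half_angle_rad(self) -> float:
        """Angular half-width of a contact patch on the carrier surface."""
        perim = ellipse_perimeter(*self.carrier_semi_axes_m)
        return min(math.pi * self.contact_width_m / perim, 0.45 * math.pi)


@dataclass(frozen=True)
class Placement:
    """In-plane carrier offset from the duct centerline plus insertion step."""

    x_offset_m: float = 0.0
    y_offset_m: float = 0.0
    insertion_step: int = 16
    grid_index: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_offset_m) and math.isfinite(self.y_offset_m)):
            raise ValueError("offsets must be finite")
        if self.insertion_step < 1:
            raise ValueError("insertion_step must be >= 1")


# ---------------------------------------------------------------------------
# centerline
# ---------------------------------------------------------------------------


@dataclass
class Centerline:
    """Sampled duct centerline with orthonormal local frames.

    ``frames[i]`` rows are (tangent t, in-plane x_hat, in-plane y_hat).
    """

    samples: np.ndarray        # (N, 3)
    frames: np.ndarray         # (N, 3, 3)
    arclength_m: np.ndarray    # (N,), strictly increasing, starts at 0

    @property
    def total_length_m(self) -> float:
        return float(self.arclength_m[-1])

    def at(self, s: np.ndarray | float):
        """Interpolate (points, frames) at arc lengths ``s``.

        Frames are linearly interpolated and re-orthonormalized, which keeps
        them continuous (no flips) since the sampling is dense.
        """
        s = np.atleast_1d(np.asarray(s, dtype=float))
        s = np.clip(s, 0.0, self.total_length_m)
        idx = np.searchsorted(self.arclength_m, s, side="right") - 1
        idx = np.clip(idx, 0, len(self.arclength_m) - 2)
        s0 = self.arclength_m[idx]
        s1 = self.arclength_m[idx + 1]
        w = ((s - s0) / (s1 - s0))[:, None]
        pts = (1 - w) * self.samples[idx] + w * self.samples[idx + 1]
        fr = (1 - w[:, :, None]) * self.frames[idx] + w[:, :, None] * self.frames[idx + 1]
        # Gram-Schmidt: t, then x orthogonal to t, then y = t x x
        t = fr[:, 0] / np.linalg.norm(fr[:, 0], axis=1, keepdims=True)
        x = fr[:, 1] - (fr[:, 1] * t).sum(axis=1, keepdims=True) * t
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        y = np.cross(t, x)
        return pts, np.stack([t, x, y], axis=1)


def build_centerline(params: CochleaParams, n_samples: int = 2049) -> Centerline:
    """Compute the duct centerline (conical helix) and its local frames.

    The radius interpolates linearly in the turn angle from base to apex and
    the axial rise is ``axial_pitch_m`` per turn.  ``x_hat`` points toward
    the spiral axis (the modiolar side), ``y_hat`` toward +z (the
    basilar-membrane side).  For ``n_turns == 0`` a straight duct of
    ``length_m`` along +z with constant frames is returned.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if params.n_turns == 0:
        L = float(params.length_m)  # validated > 0
        z = np.linspace(0.0, L, n_samples)
        samples = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        frame = np.array(
            [[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]
        )
        frames = np.broadcast_to(frame, (n_samples, 3, 3)).copy()
        return Centerline(samples=samples, frames=frames, arclength_m=z.copy())

    phi_total = TWO_PI * params.n_turns
    phi = np.linspace(0.0, phi_total, n_samples)
    r0, r1 = params.base_radius_m, params.apex_radius_m
    dr = (r1 - r0) / phi_total
    r = r0 + dr * phi
    dz = params.axial_pitch_m / TWO_PI
    cphi, sphi = np.cos(phi), np.sin(phi)
    samples = np.column_stack([r * cphi, r * sphi, dz * phi])
    d = np.column_stack(
        [dr * cphi - r * sphi, dr * sphi + r * cphi, np.full_like(phi, dz)]
    )
    speed = np.linalg.norm(d, axis=1)
    arclength = cumulative_simpson(speed, x=phi, initial=0.0)
    if np.any(np.diff(arclength) <= 0):
        raise ValueError("degenerate spiral: arc length is not strictly increasing")

    t = d / speed[:, None]
    radial_in = np.column_stack([-cphi, -sphi, np.zeros_like(phi)])
    x = radial_in - (radial_in * t).sum(axis=1, keepdims=True) * t
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    y = np.cross(t, x)
    frames = np.stack([t, x, y], axis=1)
    return Centerline(samples=samples, frames=frames, arclength_m=arclength)


# ---------------------------------------------------------------------------
# ellipse utilities
# ---------------------------------------------------------------------------


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation (relative error < 1e-9 for our
    aspect ratios)."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def point_to_ellipse_distance(points: np.ndarray, a: float, b: float) -> np.ndarray:
    """Unsigned distance from 2D points to the ellipse x^2/a^2 + y^2/b^2 = 1.

    Robust bisection on the standard Lagrange parameter (works for interior
    and exterior points); axis-aligned degeneracies handled explicitly.
    Requires a >= b > 0.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not (a >= b > 0):
        raise ValueError("requires a >= b > 0")
    px = np.abs(points[:, 0])
    py = np.abs(points[:, 1])
    dist = np.empty(len(points))

    on_axis = py < 1e-14 * b
    if np.any(on_axis):
        x0 = px[on_axis]
        c2_over_a = (a * a - b * b) / a
        d = np.empty_like(x0)
        near_vertex = x0 >= c2_over_a
        d[near_vertex] = np.abs(a - x0[near_vertex])
        if np.any(~near_vertex):
            # nearest point is off-axis for interior points near the center
            xi = x0[~near_vertex]
            if a == b:
                d[~near_vertex] = a - xi
            else:
                xe = a * a * xi / (a * a - b * b)
                ye = b * np.sqrt(np.maximum(0.0, 1.0 - (xe / a) ** 2))
                d[~near_vertex] = np.hypot(xe - xi, ye)
        dist[on_axis] = d

    gen = ~on_axis
    if np.any(gen):
        x0, y0 = px[gen], py[gen]
        # f(t) = (a x/(t+a^2))^2 + (b y/(t+b^2))^2 - 1, monotone decreasing
        lo = -b * b + b * y0  # f(lo) >= 0
        hi = np.maximum(a * x0, b * y0) + max(a, b) ** 2
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            f = (a * x0 / (mid + a * a)) ** 2 + (b * y0 / (mid + b * b)) ** 2 - 1.0
            take = f > 0
            lo = np.where(take, mid, lo)
            hi = np.where(take, hi, mid)
        t = 0.5 * (lo + hi)
        xe = a * a * x0 / (t + a * a)
        ye = b * b * y0 / (t + b * b)
        dist[gen] = np.hypot(xe - x0, ye - y0)
    return dist


def min_curve_clearance(
    inner_pts: np.ndarray, a: float, b: float, signed: bool = True
) -> float:
    """Minimum distance from sampled inner-curve points to an origin-centered
    ellipse (a, b).  Negative if any point lies outside and ``signed``."""
    d = point_to_ellipse_distance(inner_pts, a, b)
    inside = (inner_pts[:, 0] / a) ** 2 + (inner_pts[:, 1] / b) ** 2 <= 1.0
    if signed:
        d = np.where(inside, d, -d)
    return float(d.min())


def _equal_area_factor(n: int) -> float:
    """Scale factor making a regular n-gon inscribed in an ellipse enclose
    the exact ellipse area (removes the O(n^-2) volume bias of inscribed
    polygons)."""
    x = TWO_PI / n
    return math.sqrt(x / math.sin(x))


# ---------------------------------------------------------------------------
# swept ring-stack geometry description
# ---------------------------------------------------------------------------


@dataclass
class BandSpec:
    """A radial band of the cross-section: the region between consecutive
    curves.  ``region_of(s, theta)`` names the tissue (or 'void')."""

    region_of: Callable[[float, float], str]
    n_sub: int = 1
    grade_outward: bool = False  # geometric radial grading (coarser outward)
    grade_inward: bool = False   # geometric radial grading (coarser inward)


@dataclass
class SurfaceTag:
    """A labeled surface on curve ``curve_index`` restricted to an s-range
    and an angular range (radians, may wrap through 0).  ``split=True``
    marks a thin-layer interface across which mesh nodes are duplicated."""

    curve_index: int
    label: str
    s_range: Tuple[float, float]
    theta_range: Tuple[float, float]
    split: bool = False


@dataclass
class GeometryModel:
    """Labeled solid model: a ring stack swept along a centerline.

    ``curves[k](s, theta_grid) -> (n, 2)`` gives local cross-section points
    of curve k; ``bands[k]`` is the region between curve k-1 (or the local
    center for k = 0) and curve k.  The mesher consumes this directly.
    """

    centerline: Centerline
    local_center: Callable[[float], Tuple[float, float]]
    curves: List[Callable[[float, np.ndarray], np.ndarray]]
    bands: List[BandSpec]
    surfaces: List[SurfaceTag] = field(default_factory=list)
    outer_label: str = "GROUND_OUTER"
    cap_labels: Tuple[str, str] = ("GROUND_OUTER", "GROUND_OUTER")
    # optional electrode on an end cap: (end index 0|1, label, outermost curve)
    cap_contact: Optional[Tuple[int, str, int]] = None
    forced_stations: Sequence[float] = field(default_factory=tuple)
    refine_span: Optional[Tuple[float, float]] = None
    # optional cap on axial station spacing (e.g. to limit the per-station
    # twist of the swept frame on tightly curved centerlines)
    max_spacing_fn: Optional[Callable[[float], float]] = None
    theta_multiple: int = 8
    # curve whose perimeter sets the angular resolution of the mesh
    theta_ref_curve: int = 0
    band_thickness_hint: Optional[List[float]] = None
    provenance: Dict = field(default_factory=dict)
    solids: Dict[str, str] = field(default_factory=dict)
    interfaces: Dict[str, str] = field(default_factory=dict)
    clearance_m: Optional[float] = None
    params: Optional[CochleaParams] = None
    array: Optional[ElectrodeArraySpec] = None
    placement: Optional[Placement] = None

    @property
    def length_m(self) -> float:
        return self.centerline.total_length_m

    def region_names(self) -> set:
        return set(self.solids)

    def describe(self) -> str:
        """Deterministic JSON description (identical parameters produce
        byte-identical output)."""
        prov = {k: v for k, v in sorted(self.provenance.items())}
        doc = {
            "solids": dict(sorted(self.solids.items())),
            "interfaces": dict(sorted(self.interfaces.items())),
            "length_m": repr(self.length_m),
            "clearance_m": repr(self.clearance_m),
            "provenance": prov,
        }
        return json.dumps(doc, sort_keys=True)

    def analytic_channel_volume_m3(self) -> float:
        """Volume of the channel (inside the duct boundary) for straight
        geometries, by quadrature of the elliptical cross-section area."""
        ab = self.provenance.get("channel_semi_axes")
        if ab is None:
            raise ValueError("analytic channel volume only defined for channels")
        (a0, b0), (a1, b1) = ab
        L = self.length_m
        from scipy.integrate import quad

        val, _ = quad(
            lambda s: math.pi
            * (a0 + (a1 - a0) * s / L)
            * (b0 + (b1 - b0) * s / L),
            0.0,
            L,
        )
        return val


# ---------------------------------------------------------------------------
# curve factories
# ---------------------------------------------------------------------------


def _ellipse_curve(
    semi_fn: Callable[[float], Tuple[float, float]],
    center_fn: Callable[[float], Tuple[float, float]] | None = None,
):
    def curve(s: float, theta: np.ndarray) -> np.ndarray:
        a, b = semi_fn(s)
        lam = _equal_area_factor(len(theta))
        x = lam * a * np.cos(theta)
        y = lam * b * np.sin(theta)
        if center_fn is not None:
            cx, cy = center_fn(s)
            x = x + cx
            y = y + cy
        return np.column_stack([x, y])

    return curve


def _offset_curve(
    semi_fn: Callable[[float], Tuple[float, float]],
    thickness_fn: Callable[[np.ndarray], np.ndarray],
):
    """Ellipse offset outward along its normal by a per-angle thickness."""

    def curve(s: float, theta: np.ndarray) -> np.ndarray:
        a, b = semi_fn(s)
        lam = _equal_area_factor(len(theta))
        ct, st = np.cos(theta), np.sin(theta)
        x = lam * a * ct
        y = lam * b * st
        nx = ct / a
        ny = st / b
        nn = np.hypot(nx, ny)
        t = thickness_fn(theta)
        return np.column_stack([x + t * nx / nn, y + t * ny / nn])

    return curve


def _in_angular_range(theta, lo: float, hi: float):
    """Membership in the (possibly wrapping) angular interval [lo, hi).

    A span of 2*pi or more covers the whole circle.
    """
    th = np.mod(theta, TWO_PI)
    if abs(hi - lo) >= TWO_PI - 1e-12:
        return np.ones_like(th, dtype=bool) if np.ndim(th) else True
    lo = lo % TWO_PI
    hi = hi % TWO_PI
    if lo <= hi:
        return (th >= lo) & (th < hi)
    return (th >= lo) | (th < hi)


# ---------------------------------------------------------------------------
# cochlea geometry
# ---------------------------------------------------------------------------

_TRANSITION_LENGTH_M = 1.0e-3  # carrier tip -> plain duct mesh morph length


def build_cochlea_geometry(
    params: CochleaParams,
    array: ElectrodeArraySpec,
    placement: Placement,
    min_clearance_m: float = 5e-6,
    centerline: Optional[Centerline] = None,
) -> GeometryModel:
    """Assemble the labeled solid model for one carrier placement.

    Regions: scala_tympani, cochlea_wall, basilar_membrane, spiral_ligament,
    bone, carrier.  Surfaces: one CONTACT_Ei patch per inserted contact, the
    outer ground boundary, the insulated membrane surface (the membrane's
    outward face, exposed to the unmodeled space above it) and the stria
    vascularis thin-layer interface on the lateral wall.

    Raises :class:`PlacementInvalid` if the carrier clearance to the duct
    boundary anywhere along the inserted span falls below
    ``min_clearance_m``.
    """
    if placement.insertion_step > array.n_contacts:
        raise ValueError("insertion_step exceeds n_contacts")
    cl = centerline if centerline is not None else build_centerline(params)
    L = cl.total_length_m
    k = placement.insertion_step
    depth = array.insertion_depth_m(k)
    if depth >= L:
        raise PlacementInvalid(
            f"insertion depth {depth:.4g} m exceeds duct length {L:.4g} m"
        )

    ac, bc = array.carrier_semi_axes_m
    xo, yo = placement.x_offset_m, placement.y_offset_m

    def lumen(s: float) -> Tuple[float, float]:
        a, b = params.lumen_semi_axes(s, L)
        return float(a), float(b)

    # --- validity: carrier strictly inside the duct over the inserted span
    clearance = carrier_clearance(params, array, placement, L)
    if clearance < min_clearance_m:
        raise PlacementInvalid(
            f"carrier touches or crosses the duct boundary "
            f"(clearance {clearance:.3g} m < {min_clearance_m:.3g} m)"
        )

    # --- inner curve: the carrier while inserted, morphing to a small
    # centered ellipse beyond the tip (same mesh topology along the duct)
    def tip_weight(s: float) -> float:
        return min(max((s - depth) / _TRANSITION_LENGTH_M, 0.0), 1.0)

    def carrier_center(s: float) -> Tuple[float, float]:
        w = tip_weight(s)
        return (1.0 - w) * xo, (1.0 - w) * yo

    def carrier_semi(s: float) -> Tuple[float, float]:
        w = tip_weight(s)
        a, b = lumen(s)
        return (1.0 - w) * ac + w * 0.45 * a, (1.0 - w) * bc + w * 0.45 * b

    def ring_thickness(theta: np.ndarray) -> np.ndarray:
        t = np.full_like(np.asarray(theta, dtype=float), params.wall_thickness_m)
        mem = _in_angular_range(theta, TWO_PI * MEMBRANE_SECTOR_TURNS[0],
                                TWO_PI * MEMBRANE_SECTOR_TURNS[1])
        lig = _in_angular_range(theta, TWO_PI * LIGAMENT_SECTOR_TURNS[0],
                                TWO_PI * LIGAMENT_SECTOR_TURNS[1])
        t[mem] = params.membrane_thickness_m
        t[lig] = params.ligament_thickness_m
        return t

    t_max = max(
        params.wall_thickness_m,
        params.membrane_thickness_m,
        params.ligament_thickness_m,
    )
    # the bone sleeve tapers with the duct: a constant-radius sleeve would
    # exceed the centerline curvature radius near the apex (inverted sweep
    # cells) and interpenetrate the adjacent turn
    def outer_radius(s: float) -> Tuple[float, float]:
        r = lumen(s)[0] + t_max + params.bone_margin_m
        return r, r

    curves = [
        _ellipse_curve(carrier_semi, carrier_center),
        _ellipse_curve(lumen),
        _offset_curve(lumen, ring_thickness),
        _ellipse_curve(outer_radius),
    ]

    mem_lo, mem_hi = TWO_PI * MEMBRANE_SECTOR_TURNS[0], TWO_PI * MEMBRANE_SECTOR_TURNS[1]
    lig_lo, lig_hi = TWO_PI * LIGAMENT_SECTOR_TURNS[0], TWO_PI * LIGAMENT_SECTOR_TURNS[1]

    def inner_region(s: float, theta: float) -> str:
        return "carrier" if s <= depth else "scala_tympani"

    def ring_region(s: float, theta: float) -> str:
        if _in_angular_range(theta, mem_lo, mem_hi):
            return "basilar_membrane"
        if _in_angular_range(theta, lig_lo, lig_hi):
            return "spiral_ligament"
        return "cochlea_wall"

    def bone_region(s: float, theta: float) -> str:
        # the space above the membrane (toward the organ of Corti / scala
        # media) is not part of the conductive domain; its absence makes the
        # membrane's outward face an exterior, naturally insulated surface
        if _in_angular_range(theta, mem_lo, mem_hi):
            return "void"
        return "bone"

    bands = [
        BandSpec(inner_region, n_sub=2),
        BandSpec(lambda s, th: "scala_tympani", n_sub=2),
        BandSpec(ring_region, n_sub=1),
        BandSpec(bone_region, n_sub=3, grade_outward=True),
    ]

    half = array.contact_half_angle_rad()
    surfaces: List[SurfaceTag] = []
    forced = {0.0, depth, min(depth + _TRANSITION_LENGTH_M, L), L}
    for i in range(1, k + 1):
        c = array.contact_center_s(i, k)
        s0, s1 = c - array.contact_length_m / 2, c + array.contact_length_m / 2
        surfaces.append(
            SurfaceTag(
                curve_index=0,
                label=f"CONTACT_E{i}",
                s_range=(s0, s1),
                theta_range=(-half, half),
            )
        )
        forced.update((s0, s1))
    surfaces.append(
        SurfaceTag(
            curve_index=2,
            label="STRIA_INTERFACE",
            s_range=(0.0, L),
            theta_range=(lig_lo, lig_hi),
            split=True,
        )
    )

    solids = {
        "scala_tympani": "perilymph-filled duct",
        "cochlea_wall": "bony duct wall (modiolar and floor sectors)",
        "basilar_membrane": "thin resistive layer, membrane sector",
        "spiral_ligament": "lateral-wall sector",
        "bone": "surrounding bone sleeve",
        "carrier": "silicone electrode carrier (inserted span)",
    }
    for i in range(1, k + 1):
        solids[f"contact_E{i}"] = "platinum patch (surface, zero thickness)"
    interfaces = {
        "GROUND_OUTER": "outer bone boundary incl. end caps, V = 0",
        "INSULATED_MEMBRANE": "membrane outward face, zero normal flux",
        "STRIA_INTERFACE": "stria vascularis thin layer (contact impedance)",
    }

    prov = {
        "kind": "cochlea",
        "params": _dataclass_dict(params),
        "array": _dataclass_dict(array),
        "placement": _dataclass_dict(placement),
        "insertion_depth_m": repr(depth),
        "min_clearance_m": repr(min_clearance_m),
    }
    gap_hint = max(min(lumen(depth)[0] - abs(xo) - ac, lumen(depth)[1] - abs(yo) - bc),
                   2 * min_clearance_m)

    # cap the per-station twist of the swept frame at ~0.2 rad so the strong
    # apical turn rate does not shear the cells into slivers
    _MAX_TWIST_RAD = 0.2

    def max_spacing(s: float) -> float:
        pt, _ = cl.at(float(s))
        r_xy = math.hypot(float(np.atleast_2d(pt)[0, 0]),
                          float(np.atleast_2d(pt)[0, 1]))
        return _MAX_TWIST_RAD * max(r_xy, params.apex_radius_m)

    return GeometryModel(
        centerline=cl,
        local_center=carrier_center,
        curves=curves,
        bands=bands,
        surfaces=surfaces,
        outer_label="GROUND_OUTER",
        cap_labels=("GROUND_OUTER", "GROUND_OUTER"),
        forced_stations=tuple(sorted(forced)),
        refine_span=(0.0, min(depth + _TRANSITION_LENGTH_M, L)),
        max_spacing_fn=max_spacing,
        theta_multiple=16,
        theta_ref_curve=1,
        band_thickness_hint=[min(ac, bc), gap_hint, t_max, params.bone_margin_m],
        provenance=prov,
        solids=solids,
        interfaces=interfaces,
        clearance_m=clearance,
        params=params,
        array=array,
        placement=placement,
    )


def carrier_clearance(
    params: CochleaParams,
    array: ElectrodeArraySpec,
    placement: Placement,
    total_length: Optional[float] = None,
    n_s: int = 33,
    n_theta: int = 720,
) -> float:
    """Minimum signed clearance between the carrier surface and the duct
    boundary over the inserted span (negative if the carrier pokes out).

    Sampled densely in angle; for concentric aligned ellipses the minimum is
    attained exactly at the axis sample points.
    """
    if total_length is None:
        if params.n_turns == 0:
            total_length = float(params.length_m)
        else:
            total_length = build_centerline(params, n_samples=513).total_length_m
    depth = array.insertion_depth_m(placement.insertion_step)
    ac, bc = array.carrier_semi_axes_m
    xo, yo = placement.x_offset_m, placement.y_offset_m
    theta = np.arange(n_theta) * (TWO_PI / n_theta)
    pts0 = np.column_stack([ac * np.cos(theta) + xo, bc * np.sin(theta) + yo])
    best = math.inf
    for s in np.linspace(0.0, min(depth, total_length), n_s):
        a, b = params.lumen_semi_axes(s, total_length)
        best = min(best, min_curve_clearance(pts0, float(a), float(b)))
    return best


def _dataclass_dict(obj) -> Dict:
    from dataclasses import asdict

    d = asdict(obj)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in sorted(d.items())}


# ---------------------------------------------------------------------------
# proximity grid
# ---------------------------------------------------------------------------


@dataclass
class ProximityGrid:
    """Equally spaced candidate carrier placements in the local (x, y) plane.

    The spacing ``spacing_m`` is the same along both axes (the sweep
    increment ``d``); placements whose carrier would touch or cross a
    bounding layer are flagged invalid, never dropped.
    """

    spacing_m: float
    n_x: int
    n_y: int
    placements: List[Placement]
    valid: List[bool]
    clearances_m: List[float]

    def valid_placements(self) -> List[Placement]:
        return [p for p, ok in zip(self.placements, self.valid) if ok]

    def offsets(self) -> np.ndarray:
        return np.array([[p.x_offset_m, p.y_offset_m] for p in self.placements])


def make_proximity_grid(
    params: CochleaParams,
    array: ElectrodeArraySpec,
    n_x: int = 12,
    n_y: int = 12,
    insertion_step: Optional[int] = None,
    min_clearance_m: float = 5e-6,
) -> ProximityGrid:
    """Build the in-plane placement grid used by the proximity protocols.

    The grid contains the mid-scala placement (offset 0) and moves the
    carrier in equal increments ``d`` toward the walls; with ``n`` samples
    per axis the offsets are ``(i - (n-1)//2) * d`` for ``i = 0..n-1``, so
    for even ``n`` the deeper extreme (``+ (n//2) d``) lies on the positive
    side — the direction the contact patches face, i.e. the approach toward
    the cochlea wall.  The spacing is set on the wider (x) axis so that
    extreme sample sits a whisker (2 x ``min_clearance_m``) away from
    touching at the tightest inserted cross-section; samples that touch or
    cross a wall (mostly on the narrower y axis) are flagged invalid, never
    dropped.
    """
    if n_x < 1 or n_y < 1:
        raise ValueError("n_x, n_y must be >= 1")
    if insertion_step is None:
        insertion_step = array.n_contacts
    if params.n_turns == 0:
        L = float(params.length_m)
    else:
        L = build_centerline(params, n_samples=513).total_length_m
    depth = min(array.insertion_depth_m(insertion_step), L)
    a_tip, b_tip = params.lumen_semi_axes(depth, L)
    ac, bc = array.carrier_semi_axes_m
    gap_x = float(a_tip) - ac
    gap_y = float(b_tip) - bc
    if n_x > 1:
        spacing = (gap_x - 2.0 * min_clearance_m) / (n_x // 2)
    elif n_y > 1:
        spacing = (gap_y - 2.0 * min_clearance_m) / (n_y // 2)
    else:
        spacing = min(gap_x, gap_y)

    placements: List[Placement] = []
    valid: List[bool] = []
    clearances: List[float] = []
    for i in range(n_x):
        x_off = (i - (n_x - 1) // 2) * spacing
        for j in range(n_y):
            y_off = (j - (n_y - 1) // 2) * spacing
            p = Placement(
                x_offset_m=x_off,
                y_offset_m=y_off,
                insertion_step=insertion_step,
                grid_index=(i, j),
            )
            c = carrier_clearance(params, array, p, total_length=L)
            placements.append(p)
            clearances.append(c)
            valid.append(c >= min_clearance_m)
    return ProximityGrid(
        spacing_m=spacing,
        n_x=n_x,
        n_y=n_y,
        placements=placements,
        valid=valid,
        clearances_m=clearances,
    )


# ---------------------------------------------------------------------------
# toy channel (straight, uncoiled test duct)
# ---------------------------------------------------------------------------


def make_toy_channel(
    length_m: float,
    semi_axes_base_m: Tuple[float, float],
    semi_axes_end_m: Optional[Tuple[float, float]] = None,
    block_margin_m: float = 1.0e-3,
    channel_region: str = "scala_tympani",
    block_region: str = "bone",
    outer_label: str = "GROUND_OUTER",
    cap_labels: Tuple[str, str] = ("INSULATED", "GROUND_OUTER"),
    cap_contact: Optional[Tuple[int, str]] = None,
    contact_radius_m: Optional[float] = None,
    n_sub_channel: int = 3,
    n_sub_block: int = 3,
) -> GeometryModel:
    """A straight, optionally tapered elliptical channel inside a bone block.

    A fast fixture: the "uncoiled" duct.  By default the channel carries
    perilymph conductivity inside a block whose far end face is the ground.
    ``cap_contact=(end, label)`` turns the channel disc on that end cap into
    an electrode (optionally only out to ``contact_radius_m``).
    """
    if not length_m > 0:
        raise ValueError("length_m must be > 0")
    for v in semi_axes_base_m:
        if not v > 0:
            raise ValueError("semi-axes must be > 0")
    if semi_axes_end_m is None:
        semi_axes_end_m = semi_axes_base_m
    for v in semi_axes_end_m:
        if not v > 0:
            raise ValueError("semi-axes must be > 0")
    if block_margin_m < 0:
        raise ValueError("block_margin_m must be >= 0")

    params = CochleaParams(
        n_turns=0.0,
        length_m=length_m,
        st_semi_axes_base_m=tuple(
            max(semi_axes_base_m[i], semi_axes_end_m[i]) for i in (0, 1)
        ),
        st_semi_axes_apex_m=tuple(
            min(semi_axes_base_m[i], semi_axes_end_m[i]) for i in (0, 1)
        ),
    )
    cl = build_centerline(params)
    a0, b0 = semi_axes_base_m
    a1, b1 = semi_axes_end_m

    def chan_semi(s: float) -> Tuple[float, float]:
        f = s / length_m
        return a0 + (a1 - a0) * f, b0 + (b1 - b0) * f

    curves: List[Callable] = []
    bands: List[BandSpec] = []
    hints: List[float] = []

    if contact_radius_m is not None and cap_contact is not None:
        rc = contact_radius_m
        if not 0 < rc < min(a0, b0):
            raise ValueError("contact_radius_m must fit inside the channel")
        # inner disc sized to the cap electrode for clean patch resolution
        curves.append(_ellipse_curve(lambda s: (rc, rc)))
        bands.append(
            BandSpec(lambda s, th: channel_region, n_sub=max(2, n_sub_channel - 1))
        )
        hints.append(rc)
        contact_curve_index = 0
    else:
        contact_curve_index = 0

    curves.append(_ellipse_curve(chan_semi))
    bands.append(BandSpec(lambda s, th: channel_region, n_sub=n_sub_channel))
    hints.append(min(a0, b0))
    channel_curve_index = len(curves) - 1

    if block_margin_m > 0:
        outer_r = max(a0, a1, b0, b1) + block_margin_m
        curves.append(_ellipse_curve(lambda s: (outer_r, outer_r)))
        bands.append(
            BandSpec(lambda s, th: block_region, n_sub=n_sub_block, grade_outward=True)
        )
        hints.append(block_margin_m)

    cap_contact_spec = None
    if cap_contact is not None:
        end, label = cap_contact
        if end not in (0, 1):
            raise ValueError("cap_contact end must be 0 or 1")
        idx = contact_curve_index if contact_radius_m is not None else channel_curve_index
        cap_contact_spec = (end, label, idx)

    solids = {channel_region: "channel"}
    if block_margin_m > 0:
        solids[block_region] = "surrounding block"
    prov = {
        "kind": "channel",
        "length_m": repr(length_m),
        "channel_semi_axes": [list(semi_axes_base_m), list(semi_axes_end_m)],
        "block_margin_m": repr(block_margin_m),
    }
    return GeometryModel(
        centerline=cl,
        local_center=lambda s: (0.0, 0.0),
        curves=curves,
        bands=bands,
        surfaces=[],
        outer_label=outer_label,
        cap_labels=cap_labels,
        cap_contact=cap_contact_spec,
        forced_stations=(0.0, length_m),
        refine_span=None,
        theta_multiple=8,
        theta_ref_curve=channel_curve_index,
        band_thickness_hint=hints,
        provenance=prov,
        solids=solids,
        interfaces={outer_label: "grounded boundary"},
        params=params,
    )


# ---------------------------------------------------------------------------
# coaxial resistor (radial-flow test fixture)
# ---------------------------------------------------------------------------


def make_coaxial_resistor(
    length_m: float,
    r_inner_m: float,
    r_outer_m: float,
    region: str = "scala_tympani",
    r_layer_m: Optional[float] = None,
    layer_label: str = "STRIA_INTERFACE",
    contact_label: str = "CONTACT_E1",
    outer_label: str = "GROUND_OUTER",
    n_sub_annulus: int = 4,
) -> GeometryModel:
    """Coaxial resistor: cylindrical electrode at ``r_inner_m`` (the full
    inner lateral surface), grounded wall at ``r_outer_m``, insulated end
    caps.  Current flows radially; the continuum resistance is

        R = ln(r_outer / r_inner) / (2 pi sigma L)

    plus ``t / (sigma_layer * 2 pi r_layer L)`` when a full-circumference
    thin layer is placed at ``r_layer_m``.  The disc inside the electrode is
    enclosed by the equipotential surface and carries no net current.
    """
    if not (0 < r_inner_m < r_outer_m):
        raise ValueError("need 0 < r_inner_m < r_outer_m")
    if r_layer_m is not None and not (r_inner_m < r_layer_m < r_outer_m):
        raise ValueError("r_layer_m must lie strictly between the radii")
    if not length_m > 0:
        raise ValueError("length_m must be > 0")

    params = CochleaParams(
        n_turns=0.0,
        length_m=length_m,
        st_semi_axes_base_m=(r_inner_m, r_inner_m),
        st_semi_axes_apex_m=(r_inner_m, r_inner_m),
    )
    cl = build_centerline(params)

    def circ(r: float):
        return _ellipse_curve(lambda s: (r, r))

    curves: List[Callable] = [circ(r_inner_m)]
    bands: List[BandSpec] = [BandSpec(lambda s, th: region, n_sub=2)]
    hints: List[float] = [r_inner_m]
    surfaces: List[SurfaceTag] = [
        SurfaceTag(curve_index=0, label=contact_label,
                   s_range=(0.0, length_m), theta_range=(0.0, TWO_PI))
    ]
    if r_layer_m is not None:
        curves.append(circ(r_layer_m))
        bands.append(BandSpec(lambda s, th: region, n_sub=n_sub_annulus))
        hints.append(r_layer_m - r_inner_m)
        surfaces.append(
            SurfaceTag(curve_index=1, label=layer_label,
                       s_range=(0.0, length_m), theta_range=(0.0, TWO_PI),
                       split=True)
        )
    curves.append(circ(r_outer_m))
    bands.append(BandSpec(lambda s, th: region, n_sub=n_sub_annulus))
    hints.append(r_outer_m - (r_layer_m if r_layer_m is not None else r_inner_m))

    return GeometryModel(
        centerline=cl,
        local_center=lambda s: (0.0, 0.0),
        curves=curves,
        bands=bands,
        surfaces=surfaces,
        outer_label=outer_label,
        cap_labels=("INSULATED", "INSULATED"),
        forced_stations=(0.0, length_m),
        refine_span=None,
        theta_multiple=8,
        theta_ref_curve=len(curves) - 1,
        band_thickness_hint=hints,
        provenance={
            "kind": "coaxial",
            "length_m": repr(length_m),
            "r_inner_m": repr(r_inner_m),
            "r_outer_m": repr(r_outer_m),
            "r_layer_m": repr(r_layer_m),
        },
        solids={region: "annular conductor"},
        interfaces={outer_label: "grounded outer wall"},
        params=params,
    )
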