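"""Experiment drivers for the cochlear volume-conductor simulator.

Four protocols are provided:

* :func:`run_sequential_insertion` — impedance of every inserted contact is
  recorded after each insertion step (step ``k`` inserts contacts
  ``E1..Ek``), giving ``sum(1..n)`` records (136 for a 16-contact array).
* :func:`run_proximity_sweep` — the fully inserted carrier is offset across
  the scala tympani cross-section along one in-plane axis and the impedance
  of selected contacts is recorded at every valid placement.
* :func:`run_insertion_depth_profile` — per-contact impedance of the fully
  inserted, mid-scala array (one geometry, one solve per contact).
* :func:`run_conductivity_sensitivity` — a fixed proximity profile is
  recomputed under perturbed tissue conductivity and the change of the
  mid-scala-normalized profile is reported.

All drivers are deterministic: identical inputs produce bit-identical
outputs.  Sweep results are keyed by ``(grid_index, insertion_step,
contact_id)``, so record ordering never carries information.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field, is_dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .conductivity import ConductivityTable
from .fem import (
    FemSystem,
    ImpedanceRecord,
    SolverOptions,
    SourceSpec,
    compute_impedance,
    solve_potential,
)
from .geometry import (
    CochleaParams,
    ElectrodeArraySpec,
    GeometryModel,
    Placement,
    PlacementInvalid,
    ProximityGrid,
    build_cochlea_geometry,
    make_proximity_grid,
)
from .meshing import LabeledMesh, MeshOptions, generate_mesh

logger = logging.getLogger(__name__)

__all__ = [
    "ImpedanceMap",
    "SensitivityResult",
    "run_sequential_insertion",
    "run_proximity_sweep",
    "run_insertion_depth_profile",
    "run_conductivity_sensitivity",
    "depth_rank_correlation",
    "config_hash",
    "contact_label",
    "contact_number",
]


# ---------------------------------------------------------------------------
# helpers


def contact_label(contact: str) -> str:
    """Normalize ``'E7'`` / ``'CONTACT_E7'`` to the mesh surface label."""
    return contact if contact.startswith("CONTACT_") else f"CONTACT_{contact}"


def contact_number(contact: str) -> int:
    """Contact index ``i`` of ``'E{i}'`` / ``'CONTACT_E{i}'`` (E1 = apical)."""
    name = contact.rsplit("E", 1)[-1]
    return int(name)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float):
        return float(repr(obj))
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    return repr(obj)


def config_hash(config: object) -> str:
    """Stable short hash of a (nested) configuration object.

    Dataclasses, mappings, sequences and numpy scalars/arrays are canonicalized
    to sorted-key JSON before hashing, so the hash depends only on values.
    """
    payload = json.dumps(_jsonable(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _base_metadata(
    params: CochleaParams,
    array: ElectrodeArraySpec,
    cond: ConductivityTable,
    mesh_options: MeshOptions,
    solver_options: SolverOptions,
    **extra,
) -> Dict[str, object]:
    cfg = {
        "params": params,
        "array": array,
        "sigma_S_per_m": dict(cond.sigma_S_per_m),
        "stria_thickness_m": cond.stria_thickness_m,
        "mesh_options": mesh_options,
        "solver_options": solver_options,
        **{k: v for k, v in extra.items() if k != "seeds"},
    }
    meta: Dict[str, object] = {
        "config_hash": config_hash(cfg),
        "seeds": {"mesher_seed": mesh_options.mesher_seed},
    }
    meta.update(extra)
    return meta


# ---------------------------------------------------------------------------
# result containers


@dataclass
class ImpedanceMap:
    """Impedance records of a sweep, keyed by (grid index, step, contact).

    ``records`` holds one :class:`~scalasim.fem.ImpedanceRecord` per solve;
    ``metadata`` carries the grid spacing ``d``, the configuration hash and
    seeds; ``skipped`` logs placements that were not solved (carrier touching
    or crossing a wall) with the reason.
    """

    records: List[ImpedanceRecord] = field(default_factory=list)
    metadata: Dict[str, object] = field(default_factory=dict)
    skipped: List[Dict[str, object]] = field(default_factory=list)

    @staticmethod
    def key_of(record: ImpedanceRecord) -> Tuple[object, int, str]:
        p = record.placement
        grid_index = getattr(p, "grid_index", None)
        step = getattr(p, "insertion_step", None)
        return (grid_index, step, record.contact_id)

    def append(self, record: ImpedanceRecord) -> None:
        key = self.key_of(record)
        if key in self._keys():
            raise ValueError(f"duplicate impedance record key {key!r}")
        self.records.append(record)

    def _keys(self) -> set:
        return {self.key_of(r) for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def record(self, grid_index, insertion_step: int, contact: str) -> ImpedanceRecord:
        key = (grid_index, insertion_step, contact_label(contact))
        for r in self.records:
            if self.key_of(r) == key:
                return r
        raise KeyError(f"no record with key {key!r}")

    def to_dataframe(self):
        """Tidy table: one row per record, SI columns with unit suffixes."""
        import pandas as pd

        rows = []
        for r in sorted(self.records, key=lambda r: (str(self.key_of(r)[0]), self.key_of(r)[1] or 0, contact_number(r.contact_id))):
            p = r.placement
            gi = getattr(p, "grid_index", None)
            rows.append(
                {
                    "grid_i": None if gi is None else gi[0],
                    "grid_j": None if gi is None else gi[1],
                    "insertion_step": getattr(p, "insertion_step", None),
                    "contact_id": r.contact_id,
                    "x_offset_m": getattr(p, "x_offset_m", 0.0),
                    "y_offset_m": getattr(p, "y_offset_m", 0.0),
                    "I_el_A": r.I_el_A,
                    "V_el_V": r.V_el_V,
                    "Z_el_ohm": r.Z_el_ohm,
                }
            )
        columns = [
            "grid_i",
            "grid_j",
            "insertion_step",
            "contact_id",
            "x_offset_m",
            "y_offset_m",
            "I_el_A",
            "V_el_V",
            "Z_el_ohm",
        ]
        return pd.DataFrame(rows, columns=columns)


@dataclass
class SensitivityResult:
    """Impedance-profile change under tissue-conductivity perturbation.

    ``profiles_ohm[f]`` is the impedance-vs-position vector computed with the
    perturbed conductivity ``f * sigma(layer)``; ``normalized_deviation`` is
    the maximum relative change (as a fraction, not percent) of the
    mid-scala-normalized profile relative to the baseline (factor 1.0)
    normalized profile; ``absolute_shift`` is the maximum relative change of
    the raw impedances.
    """

    layer: str
    contact_id: str
    perturbation_factors: List[float]
    positions_m: List[Tuple[float, float]]
    mid_index: int
    profiles_ohm: Dict[float, List[float]]
    normalized_deviation: float
    absolute_shift: float
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if 1.0 not in self.perturbation_factors:
            raise ValueError("baseline factor 1.0 must be present")
        if not self.normalized_deviation >= 0:
            raise ValueError("normalized_deviation must be >= 0")

    @property
    def normalized_deviation_pct(self) -> float:
        return 100.0 * self.normalized_deviation

    def normalized_profile(self, factor: float) -> np.ndarray:
        z = np.asarray(self.profiles_ohm[factor], dtype=float)
        return z / z[self.mid_index]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for f in self.perturbation_factors:
            for (x, y), z in zip(self.positions_m, self.profiles_ohm[f]):
                rows.append(
                    {
                        "factor": f,
                        "contact_id": self.contact_id,
                        "x_offset_m": x,
                        "y_offset_m": y,
                        "Z_el_ohm": z,
                    }
                )
        return pd.DataFrame(
            rows, columns=["factor", "contact_id", "x_offset_m", "y_offset_m", "Z_el_ohm"]
        )


# ---------------------------------------------------------------------------
# shared solve helper


def _solve_contacts(
    mesh: LabeledMesh,
    cond: ConductivityTable,
    contacts: Sequence[str],
    placement: Placement,
    injected_current_A: float,
    inactive_mode: str,
    solver_options: SolverOptions,
) -> List[ImpedanceRecord]:
    """One solve per contact (contact active, others per ``inactive_mode``)."""
    system = FemSystem(mesh)
    records = []
    for contact in contacts:
        label = contact_label(contact)
        src = SourceSpec(
            active_contacts=(label,),
            injected_current_A=injected_current_A,
            inactive_mode=inactive_mode,
        )
        fld = solve_potential(mesh, cond, src, solver_options, system=system)
        records.append(compute_impedance(fld, label, src, placement=placement))
    return records


# ---------------------------------------------------------------------------
# protocols


def run_sequential_insertion(
    params: Optional[CochleaParams] = None,
    array: Optional[ElectrodeArraySpec] = None,
    placement_offsets: Tuple[float, float] = (0.0, 0.0),
    cond: Optional[ConductivityTable] = None,
    mesh_options: Optional[MeshOptions] = None,
    solver_options: Optional[SolverOptions] = None,
    injected_current_A: float = 34e-6,
    inactive_mode: str = "float",
) -> ImpedanceMap:
    """Record every inserted contact's impedance after each insertion step.

    At step ``k`` the geometry is rebuilt with contacts ``E1..Ek`` inside the
    duct (E1 apical) and the impedance of each inserted contact is recorded,
    for a total of ``n(n+1)/2`` records (136 for 16 contacts).

    Raises :class:`~scalasim.geometry.PlacementInvalid`, annotated with the
    offending step, if the carrier violates clearance at any step.
    """
    params = params or CochleaParams()
    array = array or ElectrodeArraySpec()
    cond = cond or ConductivityTable()
    mesh_options = mesh_options or MeshOptions.coarse()
    solver_options = solver_options or SolverOptions()

    imap = ImpedanceMap(
        metadata=_base_metadata(
            params,
            array,
            cond,
            mesh_options,
            solver_options,
            protocol="sequential_insertion",
            placement_offsets_m=list(placement_offsets),
            inactive_mode=inactive_mode,
            injected_current_A=injected_current_A,
        )
    )
    x, y = placement_offsets
    for k in range(1, array.n_contacts + 1):
        placement = Placement(x_offset_m=x, y_offset_m=y, insertion_step=k)
        try:
            geom = build_cochlea_geometry(params, array, placement)
        except PlacementInvalid as exc:
            raise PlacementInvalid(f"insertion step {k}: {exc}") from exc
        mesh = generate_mesh(geom, mesh_options)
        contacts = [f"E{i}" for i in range(1, k + 1)]
        logger.info("sequential insertion step %d: %d contacts, %d tets", k, k, mesh.n_tets)
        for rec in _solve_contacts(
            mesh, cond, contacts, placement, injected_current_A, inactive_mode, solver_options
        ):
            imap.append(rec)
    return imap


def _axis_placements(grid: ProximityGrid, axis: str) -> List[Tuple[Placement, bool, float]]:
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    out = []
    for p, ok, clr in zip(grid.placements, grid.valid, grid.clearances_m):
        other = p.y_offset_m if axis == "x" else p.x_offset_m
        if abs(other) <= 1e-15:
            out.append((p, ok, clr))
    along = 0 if axis == "x" else 1
    out.sort(key=lambda t: (t[0].x_offset_m, t[0].y_offset_m)[along])
    return out


def run_proximity_sweep(
    params: Optional[CochleaParams] = None,
    array: Optional[ElectrodeArraySpec] = None,
    grid: Optional[ProximityGrid] = None,
    axis: str = "x",
    recorded_contacts: Optional[Sequence[str]] = None,
    cond: Optional[ConductivityTable] = None,
    mesh_options: Optional[MeshOptions] = None,
    solver_options: Optional[SolverOptions] = None,
    injected_current_A: float = 34e-6,
    inactive_mode: str = "float",
) -> ImpedanceMap:
    """Impedance of selected contacts at every valid placement along one axis.

    The fully inserted carrier is offset across the duct cross-section at the
    grid placements lying on the chosen axis.  By default every contact is
    recorded on the ``x`` axis and the quartile contacts (E1, E6, E11, E16)
    on the ``y`` axis.  Invalid placements (carrier touching or crossing a
    wall) are skipped and logged, never solved.
    """
    params = params or CochleaParams()
    array = array or ElectrodeArraySpec()
    cond = cond or ConductivityTable()
    mesh_options = mesh_options or MeshOptions.coarse()
    solver_options = solver_options or SolverOptions()
    if grid is None:
        grid = make_proximity_grid(params, array)
    if recorded_contacts is None:
        if axis == "x":
            recorded_contacts = [f"E{i}" for i in range(1, array.n_contacts + 1)]
        else:
            quart = sorted({1, array.n_contacts} | {1 + round(i * (array.n_contacts - 1) / 3) for i in (1, 2)})
            recorded_contacts = [f"E{i}" for i in quart]

    imap = ImpedanceMap(
        metadata=_base_metadata(
            params,
            array,
            cond,
            mesh_options,
            solver_options,
            protocol="proximity_sweep",
            axis=axis,
            spacing_m=grid.spacing_m,
            recorded_contacts=[contact_label(c) for c in recorded_contacts],
            inactive_mode=inactive_mode,
            injected_current_A=injected_current_A,
        )
    )
    for placement, ok, clearance in _axis_placements(grid, axis):
        if not ok:
            entry = {
                "grid_index": placement.grid_index,
                "x_offset_m": placement.x_offset_m,
                "y_offset_m": placement.y_offset_m,
                "clearance_m": clearance,
                "reason": "carrier touches or crosses a bounding wall",
            }
            imap.skipped.append(entry)
            logger.warning(
                "skipping placement %s (offset %.1f um, %.1f um): %s",
                placement.grid_index,
                1e6 * placement.x_offset_m,
                1e6 * placement.y_offset_m,
                entry["reason"],
            )
            continue
        try:
            geom = build_cochlea_geometry(params, array, placement)
        except PlacementInvalid as exc:
            imap.skipped.append(
                {
                    "grid_index": placement.grid_index,
                    "x_offset_m": placement.x_offset_m,
                    "y_offset_m": placement.y_offset_m,
                    "clearance_m": clearance,
                    "reason": str(exc),
                }
            )
            logger.warning("skipping placement %s: %s", placement.grid_index, exc)
            continue
        mesh = generate_mesh(geom, mesh_options)
        for rec in _solve_contacts(
            mesh, cond, recorded_contacts, placement, injected_current_A, inactive_mode, solver_options
        ):
            imap.append(rec)
    return imap


def run_insertion_depth_profile(
    params: Optional[CochleaParams] = None,
    array: Optional[ElectrodeArraySpec] = None,
    cond: Optional[ConductivityTable] = None,
    mesh_options: Optional[MeshOptions] = None,
    solver_options: Optional[SolverOptions] = None,
    injected_current_A: float = 34e-6,
    inactive_mode: str = "float",
) -> ImpedanceMap:
    """Per-contact impedance of the fully inserted, mid-scala array.

    One geometry and mesh; one solve per contact.  Matches the final step of
    :func:`run_sequential_insertion` on the same configuration.
    """
    params = params or CochleaParams()
    array = array or ElectrodeArraySpec()
    cond = cond or ConductivityTable()
    mesh_options = mesh_options or MeshOptions.coarse()
    solver_options = solver_options or SolverOptions()

    placement = Placement(insertion_step=array.n_contacts)
    geom = build_cochlea_geometry(params, array, placement)
    mesh = generate_mesh(geom, mesh_options)
    imap = ImpedanceMap(
        metadata=_base_metadata(
            params,
            array,
            cond,
            mesh_options,
            solver_options,
            protocol="insertion_depth_profile",
            inactive_mode=inactive_mode,
            injected_current_A=injected_current_A,
        )
    )
    contacts = [f"E{i}" for i in range(1, array.n_contacts + 1)]
    for rec in _solve_contacts(
        mesh, cond, contacts, placement, injected_current_A, inactive_mode, solver_options
    ):
        imap.append(rec)
    return imap


def depth_rank_correlation(imap: ImpedanceMap) -> float:
    """Spearman correlation between apical rank and Z over a depth profile.

    Apical rank orders contacts from basal (rank 1) to apical (rank n), so a
    positive correlation means impedance grows with insertion depth.
    """
    from scipy.stats import spearmanr

    recs = sorted(imap.records, key=lambda r: contact_number(r.contact_id))
    if len(recs) < 3:
        raise ValueError("need at least 3 contacts for a rank correlation")
    apical_rank = [-contact_number(r.contact_id) for r in recs]
    z = [r.Z_el_ohm for r in recs]
    rho = spearmanr(apical_rank, z).statistic
    return float(rho)


def run_conductivity_sensitivity(
    params: Optional[CochleaParams] = None,
    array: Optional[ElectrodeArraySpec] = None,
    cond: Optional[ConductivityTable] = None,
    layer: str = "scala_tympani",
    step: float = 0.05,
    range_: float = 0.10,
    sweep: Optional[Sequence[Placement]] = None,
    contact: str = "E16",
    mesh_options: Optional[MeshOptions] = None,
    solver_options: Optional[SolverOptions] = None,
    injected_current_A: float = 34e-6,
    inactive_mode: str = "float",
) -> SensitivityResult:
    """Impedance-profile change under perturbed tissue conductivity.

    The impedance of ``contact`` is computed over a fixed proximity sweep
    (by default the valid x-axis placements of the default 12x12 grid, which
    include the mid-scala position) for the baseline conductivity table and
    for ``layer`` scaled by each factor ``1 ± step .. 1 ± range_``.  Each
    profile is normalized by its own mid-scala value and the maximum relative
    deviation from the baseline normalized profile is reported, together
    with the maximum raw-impedance shift.

    The finite-element system is assembled once per placement and refactored
    per conductivity factor, so the sweep costs one mesh per placement.
    """
    params = params or CochleaParams()
    array = array or ElectrodeArraySpec()
    cond = cond or ConductivityTable()
    mesh_options = mesh_options or MeshOptions.coarse()
    solver_options = solver_options or SolverOptions()
    cond.require([layer])
    if not (0 < step <= range_):
        raise ValueError("need 0 < step <= range_")

    n_steps = int(round(range_ / step))
    factors = sorted(round(1.0 + j * step, 12) for j in range(-n_steps, n_steps + 1))
    if 1.0 not in factors:
        raise ValueError("range_ must be an integer multiple of step")

    if sweep is None:
        grid = make_proximity_grid(params, array)
        sweep = [p for p, ok, _ in _axis_placements(grid, "x") if ok]
    sweep = list(sweep)
    positions = [(p.x_offset_m, p.y_offset_m) for p in sweep]
    mid_candidates = [
        i
        for i, (x, y) in enumerate(positions)
        if math.hypot(x, y) <= 1e-12
    ]
    if not mid_candidates:
        raise ValueError("the sweep must contain the mid-scala placement (offset 0, 0)")
    mid_index = mid_candidates[0]

    label = contact_label(contact)
    tables = {f: (cond if f == 1.0 else cond.scaled(f, [layer])) for f in factors}
    profiles: Dict[float, List[float]] = {f: [] for f in factors}
    for placement in sweep:
        geom = build_cochlea_geometry(params, array, placement)
        mesh = generate_mesh(geom, mesh_options)
        system = FemSystem(mesh)
        src = SourceSpec(
            active_contacts=(label,),
            injected_current_A=injected_current_A,
            inactive_mode=inactive_mode,
        )
        for f in factors:
            fld = solve_potential(mesh, tables[f], src, solver_options, system=system)
            rec = compute_impedance(fld, label, src, placement=placement)
            profiles[f].append(rec.Z_el_ohm)

    base = np.asarray(profiles[1.0], dtype=float)
    base_norm = base / base[mid_index]
    normalized_deviation = 0.0
    absolute_shift = 0.0
    for f in factors:
        if f == 1.0:
            continue
        z = np.asarray(profiles[f], dtype=float)
        norm = z / z[mid_index]
        normalized_deviation = max(
            normalized_deviation, float(np.max(np.abs(norm / base_norm - 1.0)))
        )
        absolute_shift = max(absolute_shift, float(np.max(np.abs(z / base - 1.0))))

    metadata = _base_metadata(
        params,
        array,
        cond,
        mesh_options,
        solver_options,
        protocol="conductivity_sensitivity",
        layer=layer,
        factors=factors,
        contact=label,
        positions_m=positions,
        inactive_mode=inactive_mode,
        injected_current_A=injected_current_A,
    )
    return SensitivityResult(
        layer=layer,
        contact_id=label,
        perturbation_factors=factors,
        positions_m=positions,
        mid_index=mid_index,
        profiles_ohm=profiles,
        normalized_deviation=normalized_deviation,
        absolute_shift=absolute_shift,
        metadata=metadata,
    )
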