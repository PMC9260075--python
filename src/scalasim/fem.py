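"""P1 finite-element solver for the quasi-static volume-conduction problem.

Solves the weak form of ``div(sigma grad V) = 0`` on a labeled tetrahedral
mesh with:

* ``V = 0`` on the ground surface (Dirichlet, eliminated),
* each active electrode contact a floating equipotential surface carrying a
  prescribed net current (one scalar unknown per contact, handled by a
  master–slave reduction that keeps the system symmetric positive definite),
* zero normal flux on all other exterior surfaces (natural condition),
* thin resistive layers (e.g. the stria vascularis) as contact-impedance
  interfaces: flux continuity with a potential jump
  ``dV = (t / sigma_layer) * j_n``, assembled from duplicated-node surface
  pairs.

Per-region unit stiffness matrices are cached so conductivity sweeps on a
fixed mesh cost one sparse re-combination plus a factorization each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .conductivity import ConductivityTable
from .meshing import LabeledMesh

__all__ = [
    "SourceSpec",
    "SolverOptions",
    "PotentialField",
    "ImpedanceRecord",
    "FemSystem",
    "SolveError",
    "solve_potential",
    "compute_impedance",
    "transfer_impedance_matrix",
    "boundary_flux_A",
    "reaction_current_A",
]


class SolveError(RuntimeError):
    """Linear solve failed (singular system or non-convergence)."""


@dataclass(frozen=True)
class SourceSpec:
    """Current injection specification.

    Each contact in ``active_contacts`` is driven as a floating
    equipotential surface carrying net current ``injected_current_A``
    (``contact_mode="equipotential"``), or as a uniform normal current
    density over the patch (``contact_mode="uniform_current"``).  Inactive
    inserted contacts are unconstrained by default (``inactive_mode=
    "float"``); ``"grounded"`` ties them to 0 V.
    """

    active_contacts: Tuple[str, ...]
    injected_current_A: float = 34e-6
    ground_label: str = "GROUND_OUTER"
    contact_mode: str = "equipotential"
    inactive_mode: str = "float"

    def __post_init__(self) -> None:
        if not self.active_contacts:
            raise ValueError("active_contacts must be non-empty")
        if not self.injected_current_A > 0:
            raise ValueError("injected_current_A must be > 0")
        if self.contact_mode not in ("equipotential", "uniform_current"):
            raise ValueError("contact_mode must be equipotential|uniform_current")
        if self.inactive_mode not in ("float", "grounded"):
            raise ValueError("inactive_mode must be float|grounded")


@dataclass(frozen=True)
class SolverOptions:
    """Linear-solver controls.

    ``method="direct"`` uses a sparse LU factorization (deterministic, and
    re-used across right-hand sides); ``"cg"`` uses conjugate gradients with
    an incomplete-LU preconditioner to relative residual ``tol``.
    """

    method: str = "direct"
    tol: float = 1e-10
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if self.method not in ("direct", "cg"):
            raise ValueError("method must be direct|cg")
        if not 0 < self.tol < 1e-2:
            raise ValueError("tol out of range")


@dataclass
class PotentialField:
    """Nodal potential solution with per-contact equipotential values."""

    values_V: np.ndarray
    contact_potentials_V: Dict[str, float]
    solve_stats: Dict
    source: SourceSpec


@dataclass(frozen=True)
class ImpedanceRecord:
    """Electrode-to-ground impedance of one contact: Z = V / I."""

    contact_id: str
    I_el_A: float
    V_el_V: float
    Z_el_ohm: float
    placement: Optional[object] = None

    def __post_init__(self) -> None:
        if self.I_el_A != 0 and self.Z_el_ohm != self.V_el_V / self.I_el_A:
            raise ValueError("Z_el_ohm must equal V_el_V / I_el_A")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _unit_stiffness(nodes: np.ndarray, tets: np.ndarray) -> sp.csr_matrix:
    """Stiffness matrix of the P1 Laplacian (unit conductivity) on ``tets``."""
    n = len(nodes)
    p = nodes[tets]
    e = p[:, 1:] - p[:, :1]                       # (m, 3, 3) edge matrix rows
    det = np.linalg.det(e)
    vol = np.abs(det) / 6.0
    inv = np.linalg.inv(e)                        # columns are grad(lambda_1..3)
    g = np.empty((len(tets), 4, 3))
    g[:, 1:] = inv.transpose(0, 2, 1)
    g[:, 0] = -g[:, 1:].sum(axis=1)
    k_loc = np.einsum("mid,mjd,m->mij", g, g, vol)
    rows = np.repeat(tets, 4, axis=1).reshape(-1)
    cols = np.tile(tets, (1, 4)).reshape(-1)
    return sp.coo_matrix((k_loc.reshape(-1), (rows, cols)), shape=(n, n)).tocsr()


def _jump_mass(nodes: np.ndarray, tris_minus: np.ndarray,
               tris_plus: np.ndarray, n: int) -> sp.csr_matrix:
    """Unit-coefficient thin-layer coupling: energy
    ``integral (V+ - V-) (w+ - w-) dS`` over matched triangle pairs."""
    p = nodes[tris_minus]
    area = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    m_ref = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
    m_loc = area[:, None, None] * m_ref
    rows, cols, vals = [], [], []
    for sa, sb, sign in (
        (tris_minus, tris_minus, 1.0),
        (tris_plus, tris_plus, 1.0),
        (tris_minus, tris_plus, -1.0),
        (tris_plus, tris_minus, -1.0),
    ):
        rows.append(np.repeat(sa, 3, axis=1).reshape(-1))
        cols.append(np.tile(sb, (1, 3)).reshape(-1))
        vals.append(sign * m_loc.reshape(-1))
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()


class FemSystem:
    """Cached per-region assembly for a fixed mesh.

    The global stiffness for any conductivity table is
    ``K = sum_r sigma_r K_r + sum_layer (sigma_layer / t) M_layer``, so
    conductivity sweeps re-use the per-region matrices.
    """

    def __init__(self, mesh: LabeledMesh):
        self.mesh = mesh
        n = mesh.n_nodes
        self.region_matrices: Dict[str, sp.csr_matrix] = {}
        for name in mesh.region_names:
            tets = mesh.tets_of_region(name)
            if len(tets):
                self.region_matrices[name] = _unit_stiffness(mesh.nodes, tets)
        self.layer_matrices: Dict[str, sp.csr_matrix] = {
            label: _jump_mass(mesh.nodes, tm, tp, n)
            for label, (tm, tp) in mesh.interface_pairs.items()
        }

    def stiffness(self, cond: ConductivityTable) -> sp.csr_matrix:
        cond.require(self.region_matrices)
        k = sum(
            (cond[name] * mat for name, mat in self.region_matrices.items()),
            start=sp.csr_matrix((self.mesh.n_nodes, self.mesh.n_nodes)),
        )
        for label, mat in self.layer_matrices.items():
            k = k + cond.stria_areal_conductance * mat
        return k.tocsr()


# ---------------------------------------------------------------------------
# constraints and solve
# ---------------------------------------------------------------------------


def _reduction(
    mesh: LabeledMesh,
    ground_nodes: np.ndarray,
    equipotential_groups: Sequence[np.ndarray],
) -> Tuple[sp.csr_matrix, List[int]]:
    """Master–slave reduction matrix P (n_nodes x n_reduced).

    Ground nodes are eliminated; each equipotential group collapses to a
    single reduced dof.  Returns P and the reduced index of each group.
    """
    n = mesh.n_nodes
    owner = -np.ones(n, dtype=np.int64)  # -2 = eliminated, g >= 0 = group g
    # structured nodes not referenced by any element (e.g. inside dropped
    # void cells) carry no stiffness; eliminate them with the ground
    referenced = np.zeros(n, dtype=bool)
    referenced[np.unique(mesh.tets)] = True
    owner[~referenced] = -2
    owner[ground_nodes] = -2
    for g, nodes in enumerate(equipotential_groups):
        clash = owner[nodes] == -2
        if np.any(clash):
            raise SolveError("equipotential contact intersects the ground surface")
        owner[nodes] = g
    free = np.nonzero(owner == -1)[0]
    n_red = len(free) + len(equipotential_groups)
    col = np.full(n, -1, dtype=np.int64)
    col[free] = np.arange(len(free))
    group_cols = [len(free) + g for g in range(len(equipotential_groups))]
    for g, nodes in enumerate(equipotential_groups):
        col[nodes] = group_cols[g]
    keep = col >= 0
    p = sp.coo_matrix(
        (np.ones(keep.sum()), (np.nonzero(keep)[0], col[keep])),
        shape=(n, n_red),
    ).tocsr()
    return p, group_cols


def _solve_reduced(k_red: sp.csr_matrix, rhs: np.ndarray,
                   opts: SolverOptions) -> Tuple[np.ndarray, Dict]:
    k_red = k_red.tocsc()
    if opts.method == "direct":
        try:
            lu = spla.splu(k_red)
        except RuntimeError as exc:  # singular factorization
            raise SolveError(f"singular system: {exc}") from exc
        u = lu.solve(rhs)
        res = np.linalg.norm(k_red @ u - rhs) / max(np.linalg.norm(rhs), 1e-300)
        stats = {"method": "direct", "iterations": 1, "residual": float(res)}
        if not np.all(np.isfinite(u)):
            raise SolveError("direct solve produced non-finite values")
        return u, stats
    try:
        ilu = spla.spilu(k_red, drop_tol=1e-5, fill_factor=20)
        prec = spla.LinearOperator(k_red.shape, ilu.solve)
    except RuntimeError as exc:
        raise SolveError(f"preconditioner failed: {exc}") from exc
    it = {"n": 0}

    def cb(_):
        it["n"] += 1

    u, info = spla.cg(k_red, rhs, rtol=opts.tol, atol=0.0,
                      maxiter=opts.max_iter, M=prec, callback=cb)
    res = np.linalg.norm(k_red @ u - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if info != 0 or res > opts.tol * 10:
        raise SolveError(
            f"cg failed to converge: info={info}, residual={res:.3e} "
            f"after {it['n']} iterations"
        )
    return u, {"method": "cg", "iterations": it["n"], "residual": float(res)}


def _contact_node_groups(mesh: LabeledMesh, labels: Iterable[str]) -> List[np.ndarray]:
    groups = []
    for lab in labels:
        nodes = mesh.nodes_of_label(lab)
        if len(nodes) == 0:
            raise SolveError(f"contact {lab!r} has no mesh surface")
        groups.append(nodes)
    return groups


def _patch_node_weights(mesh: LabeledMesh, label: str) -> np.ndarray:
    """Area-lumped node weights of a surface patch, normalized to sum 1."""
    tris = mesh.tris_of_label(label)
    areas = mesh.tri_areas(tris)
    w = np.zeros(mesh.n_nodes)
    np.add.at(w, tris.reshape(-1), np.repeat(areas / 3.0, 3))
    return w / w.sum()


def solve_potential(
    mesh: LabeledMesh,
    cond: ConductivityTable,
    src: SourceSpec,
    opts: Optional[SolverOptions] = None,
    system: Optional[FemSystem] = None,
) -> PotentialField:
    """Solve for the potential with the given source specification.

    Passing a pre-built :class:`FemSystem` re-uses the per-region assembly
    (useful in conductivity sweeps).
    """
    opts = opts or SolverOptions()
    for lab in src.active_contacts:
        if lab not in mesh.boundary_names:
            raise SolveError(f"active contact {lab!r} not present in mesh")
    if src.ground_label not in mesh.boundary_names:
        raise SolveError(f"no ground surface {src.ground_label!r} in mesh")

    sys_ = system or FemSystem(mesh)
    k = sys_.stiffness(cond)

    ground_nodes = mesh.nodes_of_label(src.ground_label)
    if src.inactive_mode == "grounded":
        inactive = [c for c in mesh.contact_labels()
                    if c not in src.active_contacts]
        if inactive:
            ground_nodes = np.unique(np.concatenate(
                [ground_nodes] + [mesh.nodes_of_label(c) for c in inactive]
            ))

    n = mesh.n_nodes
    rhs_full = np.zeros(n)
    if src.contact_mode == "equipotential":
        groups = _contact_node_groups(mesh, src.active_contacts)
        p, group_cols = _reduction(mesh, ground_nodes, groups)
        rhs = p.T @ rhs_full
        for gc in group_cols:
            rhs[gc] += src.injected_current_A
    else:
        for lab in src.active_contacts:
            rhs_full += src.injected_current_A * _patch_node_weights(mesh, lab)
        p, group_cols = _reduction(mesh, ground_nodes, [])
        rhs = p.T @ rhs_full

    k_red = (p.T @ k @ p).tocsc()
    u_red, stats = _solve_reduced(k_red, rhs, opts)
    u = p @ u_red

    contact_v: Dict[str, float] = {}
    if src.contact_mode == "equipotential":
        for lab, gc in zip(src.active_contacts, group_cols):
            contact_v[lab] = float(u_red[gc])
    else:
        for lab in src.active_contacts:
            w = _patch_node_weights(mesh, lab)
            contact_v[lab] = float(w @ u)

    stats["n_dofs"] = k_red.shape[0]
    return PotentialField(values_V=u, contact_potentials_V=contact_v,
                          solve_stats=stats, source=src)


def compute_impedance(field: PotentialField, contact_id: str,
                      src: Optional[SourceSpec] = None,
                      placement=None) -> ImpedanceRecord:
    """Electrode-to-ground impedance Z = V_el / I_el of an active contact."""
    src = src or field.source
    if contact_id not in field.contact_potentials_V:
        raise KeyError(f"contact {contact_id!r} not active in this field")
    v = field.contact_potentials_V[contact_id]
    i = src.injected_current_A
    return ImpedanceRecord(contact_id=contact_id, I_el_A=i, V_el_V=v,
                           Z_el_ohm=v / i, placement=placement)


def transfer_impedance_matrix(
    mesh: LabeledMesh,
    cond: ConductivityTable,
    contacts: Optional[Sequence[str]] = None,
    injected_current_A: float = 34e-6,
    ground_label: str = "GROUND_OUTER",
    opts: Optional[SolverOptions] = None,
    system: Optional[FemSystem] = None,
) -> Tuple[np.ndarray, List[str]]:
    """Transfer impedance matrix Z[i, j] = V at contact i per unit current
    injected at contact j (in ohms for the given current).

    All contacts are reduced to equipotential master dofs simultaneously, so
    one factorization serves every column; the result is symmetric to
    numerical precision by construction (self-adjoint operator).
    """
    opts = opts or SolverOptions()
    contacts = list(contacts) if contacts is not None else mesh.contact_labels()
    if not contacts:
        raise SolveError("no contacts in mesh")
    sys_ = system or FemSystem(mesh)
    k = sys_.stiffness(cond)
    ground_nodes = mesh.nodes_of_label(ground_label)
    groups = _contact_node_groups(mesh, contacts)
    p, group_cols = _reduction(mesh, ground_nodes, groups)
    k_red = (p.T @ k @ p).tocsc()
    try:
        lu = spla.splu(k_red)
    except RuntimeError as exc:
        raise SolveError(f"singular system: {exc}") from exc
    z = np.empty((len(contacts), len(contacts)))
    for j, gc in enumerate(group_cols):
        rhs = np.zeros(k_red.shape[0])
        rhs[gc] = injected_current_A
        u = lu.solve(rhs)
        z[:, j] = u[group_cols] / injected_current_A
    return z, contacts


def reaction_current_A(
    field: PotentialField,
    mesh: LabeledMesh,
    cond: ConductivityTable,
    label: str,
    system: Optional[FemSystem] = None,
) -> float:
    """Net current (A) leaving the domain through a labeled surface, from the
    Galerkin-consistent boundary flux (the residual K u at the surface nodes).

    This is the variationally exact discrete flux; it conserves current to
    solver tolerance.  :func:`boundary_flux_A` integrates the raw element
    gradients instead and converges under refinement.
    """
    sys_ = system or FemSystem(mesh)
    k = sys_.stiffness(cond)
    nodes = mesh.nodes_of_label(label)
    if len(nodes) == 0:
        raise KeyError(f"no boundary nodes with label {label!r}")
    return float(-(k @ field.values_V)[nodes].sum())


def boundary_flux_A(
    field: PotentialField,
    mesh: LabeledMesh,
    cond: ConductivityTable,
    label: str,
) -> float:
    """Net current (A) leaving the domain through a labeled surface,
    integrated from the piecewise-constant flux of the adjacent elements."""
    tris = mesh.tris_of_label(label)
    if len(tris) == 0:
        raise KeyError(f"no boundary triangles with label {label!r}")
    # match each labeled triangle to its (unique exterior) adjacent tet
    tet_faces = mesh.tets[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]]
    tf = np.sort(tet_faces.reshape(-1, 3), axis=1)
    order = np.lexsort(tf.T[::-1])
    tf_sorted = tf[order]
    owner_tet = order // 4
    q = np.sort(tris, axis=1)
    # find any matching face occurrence (exterior faces occur once; interface
    # faces such as contacts occur twice -- take the first, flux continuity
    # makes the side immaterial up to discretization error)
    idx = np.searchsorted(
        tf_sorted.view([("a", tf.dtype), ("b", tf.dtype), ("c", tf.dtype)]).ravel(),
        np.ascontiguousarray(q).view(
            [("a", q.dtype), ("b", q.dtype), ("c", q.dtype)]
        ).ravel(),
    )
    if np.any(idx >= len(tf_sorted)) or np.any(
        (tf_sorted[np.minimum(idx, len(tf_sorted) - 1)] != q).any(axis=1)
    ):
        raise SolveError("boundary triangle without adjacent tetrahedron")
    tets_adj = mesh.tets[owner_tet[idx]]

    # element gradients
    p = mesh.nodes[tets_adj]
    e = p[:, 1:] - p[:, :1]
    inv = np.linalg.inv(e)
    g = np.empty((len(tets_adj), 4, 3))
    g[:, 1:] = inv.transpose(0, 2, 1)
    g[:, 0] = -g[:, 1:].sum(axis=1)
    grad_v = np.einsum("mi,mid->md", field.values_V[tets_adj], g)

    sigma_codes = mesh.tet_regions[owner_tet[idx]]
    sigma = np.array([cond[mesh.region_names[c]] for c in sigma_codes])

    tp = mesh.nodes[tris]
    nvec = 0.5 * np.cross(tp[:, 1] - tp[:, 0], tp[:, 2] - tp[:, 0])
    # orient outward from the adjacent tet
    tet_cen = p.mean(axis=1)
    tri_cen = tp.mean(axis=1)
    sign = np.sign(np.einsum("md,md->m", nvec, tri_cen - tet_cen))
    nvec *= sign[:, None]
    return float(np.einsum("m,md,md->", -sigma, grad_v, nvec))
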