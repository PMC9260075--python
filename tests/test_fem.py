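import numpy as np
import pytest

from scalasim.conductivity import ConductivityTable
from scalasim.fem import (
    FemSystem,
    SolverOptions,
    SourceSpec,
    compute_impedance,
    reaction_current_A,
    solve_potential,
    transfer_impedance_matrix,
)
from scalasim.validation import bar_resistance


I_DEFAULT = 34e-6


def _solve(mesh, cond, contact, **src_kwargs):
    src = SourceSpec(active_contacts=(contact,), **src_kwargs)
    field = solve_potential(mesh, cond, src)
    return compute_impedance(field, contact, src), field, src


def test_bar_matches_oracle_exactly(bar_mesh, cond):
    # a uniform axial field is in the P1 space, so the FEM answer is exact
    rec, _, _ = _solve(bar_mesh, cond, "CONTACT_E1")
    sigma = cond["scala_tympani"]
    area = bar_mesh.tris_of_label("GROUND_OUTER")
    oracle = bar_resistance(sigma, 4e-3, np.pi * 1e-3 * 1e-3)
    assert rec.Z_el_ohm == pytest.approx(oracle, rel=1e-8)


def test_global_sigma_scaling_scales_impedance(cochlea_mesh, cond):
    rec1, _, _ = _solve(cochlea_mesh, cond, "CONTACT_E16")
    rec2, _, _ = _solve(cochlea_mesh, cond.scaled(2.0), "CONTACT_E16")
    assert rec2.Z_el_ohm == pytest.approx(rec1.Z_el_ohm / 2.0, rel=1e-10)


def test_impedance_invariant_under_current_magnitude(cochlea_mesh, cond):
    rec1, _, _ = _solve(cochlea_mesh, cond, "CONTACT_E8", injected_current_A=I_DEFAULT)
    rec2, _, _ = _solve(cochlea_mesh, cond, "CONTACT_E8", injected_current_A=1e-3)
    assert rec2.Z_el_ohm == pytest.approx(rec1.Z_el_ohm, rel=1e-10)


def test_transfer_matrix_symmetric_and_passive(cochlea_mesh, cond):
    contacts = ["CONTACT_E1", "CONTACT_E6", "CONTACT_E11", "CONTACT_E16"]
    Z, labels = transfer_impedance_matrix(cochlea_mesh, cond, contacts=contacts)
    assert labels == contacts
    asym = np.abs(Z - Z.T).max() / np.abs(Z).max()
    assert asym < 1e-6  # reciprocity
    assert np.all(np.diag(Z) > 0)
    # mutual impedances are positive and below the self impedances
    assert np.all(Z > 0)
    for i in range(len(contacts)):
        for j in range(len(contacts)):
            if i != j:
                assert Z[i, j] < min(Z[i, i], Z[j, j])


def test_discrete_maximum_principle(cochlea_mesh, cond):
    rec, field, _ = _solve(cochlea_mesh, cond, "CONTACT_E16")
    v_active = field.contact_potentials_V["CONTACT_E16"]
    assert v_active > 0
    # potential is extremal on the source and the ground
    assert field.values_V.max() <= v_active * (1 + 1e-9)
    assert field.values_V.min() >= -1e-9 * v_active


def test_reaction_current_conservation(cochlea_mesh, cond):
    rec, field, _ = _solve(cochlea_mesh, cond, "CONTACT_E1")
    i_ground = reaction_current_A(field, cochlea_mesh, cond, "GROUND_OUTER")
    assert abs(abs(i_ground) - I_DEFAULT) / I_DEFAULT < 1e-8


def test_cg_matches_direct(cochlea_mesh, cond):
    src = SourceSpec(active_contacts=("CONTACT_E16",))
    direct = solve_potential(mesh=cochlea_mesh, cond=cond, src=src)
    cg = solve_potential(
        mesh=cochlea_mesh,
        cond=cond,
        src=src,
        opts=SolverOptions(method="cg", tol=1e-10),
    )
    zd = direct.contact_potentials_V["CONTACT_E16"]
    zc = cg.contact_potentials_V["CONTACT_E16"]
    assert zc == pytest.approx(zd, rel=1e-6)


def test_grounded_inactive_contacts_lower_impedance(cochlea_mesh, cond):
    rec_float, _, _ = _solve(cochlea_mesh, cond, "CONTACT_E8", inactive_mode="float")
    rec_gnd, _, _ = _solve(cochlea_mesh, cond, "CONTACT_E8", inactive_mode="grounded")
    # grounded neighbors provide extra return paths
    assert rec_gnd.Z_el_ohm < rec_float.Z_el_ohm


def test_stria_thin_layer_affects_solution(cochlea_mesh, cond):
    # thickening the stria layer lowers its conductance and raises impedance
    thick = ConductivityTable(
        sigma_S_per_m=dict(cond.sigma_S_per_m), stria_thickness_m=300e-6
    )
    rec_base, _, _ = _solve(cochlea_mesh, cond, "CONTACT_E16")
    rec_thick, _, _ = _solve(cochlea_mesh, thick, "CONTACT_E16")
    assert rec_thick.Z_el_ohm > rec_base.Z_el_ohm
    assert thick.stria_areal_conductance == pytest.approx(
        cond.stria_areal_conductance / 10.0
    )


def test_conductivity_table_validation():
    with pytest.raises(ValueError):
        ConductivityTable(sigma_S_per_m={"bone": -1.0})
    with pytest.raises(KeyError):
        ConductivityTable().require(["unknown_tissue"])


def test_source_spec_validation():
    with pytest.raises(ValueError):
        SourceSpec(active_contacts=())
    with pytest.raises(ValueError):
        SourceSpec(active_contacts=("CONTACT_E1",), injected_current_A=-1.0)


def test_fem_system_reuse_matches_fresh_solve(cochlea_mesh, cond):
    system = FemSystem(cochlea_mesh)
    src = SourceSpec(active_contacts=("CONTACT_E4",))
    f1 = solve_potential(cochlea_mesh, cond, src, system=system)
    f2 = solve_potential(cochlea_mesh, cond, src)
    assert np.array_equal(f1.values_V, f2.values_V)
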