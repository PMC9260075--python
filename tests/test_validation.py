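import math

import numpy as np
import pytest

from scalasim.validation import (
    ConvergenceReport,
    bar_resistance,
    coaxial_resistance,
    concentric_spheres_resistance,
    disk_spreading_resistance,
    sphere_shell_mesh,
)


def test_oracle_formulas():
    sigma = 1.43
    assert disk_spreading_resistance(sigma, 5e-4) == pytest.approx(
        1.0 / (4 * sigma * 5e-4)
    )
    a, b = 1e-3, 4e-3
    assert concentric_spheres_resistance(sigma, a, b) == pytest.approx(
        (1 / a - 1 / b) / (4 * math.pi * sigma)
    )
    assert bar_resistance(sigma, 4e-3, 1e-6) == pytest.approx(4e-3 / (sigma * 1e-6))
    # a coaxial resistance with a thin layer exceeds the bare one
    bare = coaxial_resistance(sigma, 1e-3, 2e-3, 5e-3)
    lossy = coaxial_resistance(
        sigma, 1e-3, 2e-3, 5e-3, layer_areal_resistance=1e-3, r_layer=1.5e-3
    )
    assert lossy > bare > 0


def test_sphere_shell_mesh_geometry():
    a, b, n = 1e-3, 2e-3, 6
    mesh = sphere_shell_mesh(a, b, n_surface=n, n_radial=n)
    analytic = 4.0 / 3.0 * math.pi * (b**3 - a**3)
    assert mesh.total_volume_m3() == pytest.approx(analytic, rel=0.05)
    # nodes lie between the two radii
    r = np.linalg.norm(mesh.nodes, axis=1)
    assert r.min() == pytest.approx(a, rel=1e-9)
    assert r.max() == pytest.approx(b, rel=1e-9)
    # inner surface is the contact, outer is ground
    assert "CONTACT_E1" in mesh.boundary_names
    assert "GROUND_OUTER" in mesh.boundary_names


def test_sphere_shell_mesh_is_conforming():
    mesh = sphere_shell_mesh(1e-3, 2e-3, n_surface=4, n_radial=3)
    faces = {}
    for tet in mesh.tets:
        for f in (
            (tet[0], tet[1], tet[2]),
            (tet[0], tet[1], tet[3]),
            (tet[0], tet[2], tet[3]),
            (tet[1], tet[2], tet[3]),
        ):
            faces[tuple(sorted(f))] = faces.get(tuple(sorted(f)), 0) + 1
    counts = set(faces.values())
    # every face is shared by exactly two tets or lies on the boundary
    assert counts <= {1, 2}
    n_boundary_faces = sum(1 for c in faces.values() if c == 1)
    assert n_boundary_faces == len(mesh.boundary_tris)


def test_convergence_report_validation():
    with pytest.raises(ValueError):
        ConvergenceReport(h_m=[1e-3, 2e-3], Z_ohm=[1.0, 2.0])  # h not decreasing
    with pytest.raises(ValueError):
        ConvergenceReport(h_m=[2e-3, 1e-3], Z_ohm=[1.0])  # length mismatch
    rep = ConvergenceReport(
        h_m=[2e-3, 1e-3],
        Z_ohm=[1.0, 1.1],
        oracle_ohm=1.2,
        rel_errors=[abs(1.0 / 1.2 - 1), abs(1.1 / 1.2 - 1)],
        label="demo",
    )
    assert "demo" in rep.to_text()
    assert rep.to_json_dict()["oracle_ohm"] == 1.2


def test_oracle_reports_structure(oracle_reports):
    assert set(oracle_reports) == {"bar", "spheres", "disk"}
    for name, rep in oracle_reports.items():
        assert len(rep.h_m) >= 3
        assert all(z > 0 for z in rep.Z_ohm)
        assert rep.oracle_ohm and rep.oracle_ohm > 0
        assert len(rep.rel_errors) == len(rep.Z_ohm)
    # error decreases under refinement for the curved-domain studies
    assert oracle_reports["spheres"].rel_errors[-1] < oracle_reports["spheres"].rel_errors[0]
    assert oracle_reports["disk"].rel_errors[-1] < oracle_reports["disk"].rel_errors[0]
    # second-order convergence on the smooth spheres problem
    assert oracle_reports["spheres"].observed_order > 1.5
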