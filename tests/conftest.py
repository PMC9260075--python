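"""Shared fixtures.

The expensive pipeline products (meshes, protocol runs, oracle studies) are
session-scoped so each is computed once and shared between the unit tests and
the acceptance tests.
"""

from __future__ import annotations

import pytest

from scalasim.conductivity import ConductivityTable
from scalasim.geometry import (
    CochleaParams,
    ElectrodeArraySpec,
    Placement,
    build_cochlea_geometry,
    make_proximity_grid,
    make_toy_channel,
)
from scalasim.meshing import MeshOptions, generate_mesh
from scalasim.protocols import (
    run_conductivity_sensitivity,
    run_insertion_depth_profile,
    run_proximity_sweep,
    run_sequential_insertion,
)
from scalasim.validation import run_oracle_suite


@pytest.fixture(scope="session")
def params() -> CochleaParams:
    return CochleaParams()


@pytest.fixture(scope="session")
def array() -> ElectrodeArraySpec:
    return ElectrodeArraySpec()


@pytest.fixture(scope="session")
def cond() -> ConductivityTable:
    return ConductivityTable()


@pytest.fixture(scope="session")
def cochlea_mesh(params, array):
    """Fully inserted, mid-scala cochlea at the default coarse resolution."""
    geom = build_cochlea_geometry(params, array, Placement())
    return generate_mesh(geom, MeshOptions.coarse())


@pytest.fixture(scope="session")
def bar_mesh():
    """Small straight elliptical bar: one cap contact, other cap grounded."""
    geom = make_toy_channel(
        length_m=4e-3,
        semi_axes_base_m=(1e-3, 1e-3),
        block_margin_m=0.0,
        outer_label="INSULATED",
        cap_labels=("INSULATED", "GROUND_OUTER"),
        cap_contact=(0, "CONTACT_E1"),
    )
    return generate_mesh(
        geom, MeshOptions(target_size_near_m=5e-4, target_size_far_m=5e-4)
    )


@pytest.fixture(scope="session")
def proximity_grid(params, array):
    return make_proximity_grid(params, array)


@pytest.fixture(scope="session")
def depth_map(params, array, cond):
    return run_insertion_depth_profile(params, array, cond)


@pytest.fixture(scope="session")
def sequential_map(params, array, cond):
    return run_sequential_insertion(params, array, cond=cond)


@pytest.fixture(scope="session")
def proximity_x_map(params, array, cond):
    """x-axis proximity sweep recording the apical and basal end contacts."""
    return run_proximity_sweep(
        params, array, axis="x", recorded_contacts=("E1", "E16"), cond=cond
    )


@pytest.fixture(scope="session")
def sensitivity_result(params, array, cond):
    return run_conductivity_sensitivity(params, array, cond=cond)


@pytest.fixture(scope="session")
def oracle_reports():
    return run_oracle_suite()
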