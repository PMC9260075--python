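import math

import numpy as np
import pytest

from scalasim.geometry import Placement, build_cochlea_geometry, make_toy_channel
from scalasim.meshing import MeshOptions, generate_mesh, mesh_quality_report


def test_mesh_generation_is_deterministic(params, array):
    geom = build_cochlea_geometry(params, array, Placement())
    opts = MeshOptions.coarse()
    m1 = generate_mesh(geom, opts)
    m2 = generate_mesh(geom, opts)
    assert np.array_equal(m1.nodes, m2.nodes)
    assert np.array_equal(m1.tets, m2.tets)
    assert np.array_equal(m1.tet_regions, m2.tet_regions)
    assert m1.region_names == m2.region_names
    assert np.array_equal(m1.boundary_tris, m2.boundary_tris)


def test_toy_channel_volume_conservation():
    # straight cylindrical channel in a circular sleeve: volumes are analytic
    L, r, margin = 4e-3, 1e-3, 1e-3
    geom = make_toy_channel(L, (r, r), block_margin_m=margin)
    mesh = generate_mesh(geom, MeshOptions(target_size_near_m=3e-4, target_size_far_m=3e-4))
    channel = mesh.region_volume_m3("scala_tympani")
    total = mesh.total_volume_m3()
    # faceting tolerance covers the circle sagitta error
    assert channel == pytest.approx(math.pi * r * r * L, rel=0.02)
    assert total == pytest.approx(math.pi * (r + margin) ** 2 * L, rel=0.02)
    # the mesh partitions its own convex hull exactly: sum of parts = total
    assert channel + mesh.region_volume_m3("bone") == pytest.approx(total, rel=1e-12)


def test_cochlea_mesh_regions_and_labels(cochlea_mesh):
    assert set(cochlea_mesh.region_names) >= {
        "carrier",
        "scala_tympani",
        "cochlea_wall",
        "basilar_membrane",
        "spiral_ligament",
        "bone",
    }
    assert "GROUND_OUTER" in cochlea_mesh.boundary_names
    assert cochlea_mesh.contact_labels() == [f"CONTACT_E{i}" for i in range(1, 17)]
    # the stria is a split thin-layer interface, never a meshed solid
    assert "stria_vascularis" not in cochlea_mesh.region_names
    assert "STRIA_INTERFACE" in cochlea_mesh.interface_pairs


def test_cochlea_mesh_quality(cochlea_mesh):
    report = mesh_quality_report(cochlea_mesh)
    assert report["n_tets"] == cochlea_mesh.n_tets
    assert report["quality_min"] > 0.005  # no degenerate slivers
    assert report["quality_median"] > 0.3
    vols = cochlea_mesh.tet_volumes()
    assert np.all(vols > 0)


def test_contact_patches_have_comparable_areas(cochlea_mesh, array):
    nominal = array.contact_length_m * array.contact_width_m
    areas = [
        cochlea_mesh.tri_areas(cochlea_mesh.tris_of_label(lab)).sum()
        for lab in cochlea_mesh.contact_labels()
    ]
    for a in areas:
        # patches are curved and quantized to the angular grid
        assert 0.5 * nominal < a < 2.0 * nominal
    assert max(areas) / min(areas) < 1.5


def test_mesh_options_validation():
    with pytest.raises(ValueError):
        MeshOptions(target_size_near_m=-1e-4)
    with pytest.raises(ValueError):
        MeshOptions(target_size_near_m=1e-3, target_size_far_m=5e-4)


def test_coarse_preset_is_coarser_than_custom_fine(params, array):
    geom = build_cochlea_geometry(params, array, Placement())
    coarse = generate_mesh(geom, MeshOptions.coarse())
    finer = generate_mesh(
        geom,
        MeshOptions(target_size_near_m=2.5e-4, target_size_far_m=6e-4),
    )
    assert finer.n_tets > coarse.n_tets
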