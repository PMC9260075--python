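import math

import numpy as np
import pytest

from scalasim.geometry import (
    CochleaParams,
    ElectrodeArraySpec,
    Placement,
    PlacementInvalid,
    build_centerline,
    build_cochlea_geometry,
    ellipse_perimeter,
    point_to_ellipse_distance,
)


def test_centerline_accommodates_full_insertion(params, array):
    cl = build_centerline(params)
    assert cl.total_length_m > array.insertion_depth_m(array.n_contacts)
    # arc length is strictly increasing from zero
    assert cl.arclength_m[0] == 0.0
    assert np.all(np.diff(cl.arclength_m) > 0)


def test_straight_duct_length_matches_request():
    straight = CochleaParams(n_turns=0, length_m=0.02)
    assert build_centerline(straight).total_length_m == pytest.approx(0.02, rel=1e-6)


def test_insertion_depth_monotone_in_step(array):
    depths = [array.insertion_depth_m(k) for k in range(1, array.n_contacts + 1)]
    assert all(b > a for a, b in zip(depths, depths[1:]))
    assert depths[-1] <= 0.03  # the array fits in a cochlear-scale duct


def test_geometry_has_one_contact_patch_per_inserted_contact(params, array):
    for k in (1, 5, 16):
        geom = build_cochlea_geometry(params, array, Placement(insertion_step=k))
        contacts = [t for t in geom.surfaces if t.label.startswith("CONTACT_")]
        assert len(contacts) == k


def test_far_offset_placement_is_rejected(params, array):
    with pytest.raises(PlacementInvalid):
        build_cochlea_geometry(params, array, Placement(x_offset_m=5e-3))


def test_placement_validates_inputs():
    with pytest.raises(ValueError):
        Placement(x_offset_m=float("nan"))
    with pytest.raises(ValueError):
        Placement(insertion_step=0)


def test_proximity_grid_shape_and_flags(proximity_grid):
    g = proximity_grid
    assert g.n_x == g.n_y == 12
    assert len(g.placements) == len(g.valid) == len(g.clearances_m)
    assert g.spacing_m > 0
    # the grid keeps invalid candidates, flagged rather than dropped
    assert any(g.valid) and not all(g.valid)
    # mid-scala placement is present and valid
    mids = [
        ok
        for p, ok in zip(g.placements, g.valid)
        if p.x_offset_m == 0.0 and p.y_offset_m == 0.0
    ]
    assert mids == [True]


def test_proximity_grid_spacing_uniform(proximity_grid):
    xs = sorted({p.x_offset_m for p in proximity_grid.placements})
    ys = sorted({p.y_offset_m for p in proximity_grid.placements})
    assert len(xs) == len(ys) == 12
    assert np.allclose(np.diff(xs), proximity_grid.spacing_m, rtol=1e-12)
    assert np.allclose(np.diff(ys), proximity_grid.spacing_m, rtol=1e-12)


def test_invalid_grid_placements_have_smallest_clearance(proximity_grid):
    clear_valid = [
        c for c, ok in zip(proximity_grid.clearances_m, proximity_grid.valid) if ok
    ]
    clear_invalid = [
        c for c, ok in zip(proximity_grid.clearances_m, proximity_grid.valid) if not ok
    ]
    assert min(clear_valid) > max(clear_invalid)


def test_ellipse_helpers():
    # circle specializations
    assert ellipse_perimeter(1.0, 1.0) == pytest.approx(2 * math.pi, rel=1e-6)
    d = point_to_ellipse_distance(np.array([[0.0, 0.0], [2.0, 0.0]]), 2.0, 1.0)
    assert d[0] == pytest.approx(1.0, rel=1e-9)  # center -> minor vertex
    assert d[1] == pytest.approx(0.0, abs=1e-9)  # on-curve point


def test_array_spec_defaults_and_validation():
    a = ElectrodeArraySpec()
    assert a.n_contacts == 16
    assert a.contact_ids[0] == "E1" and a.contact_ids[-1] == "E16"
    with pytest.raises(ValueError):
        ElectrodeArraySpec(n_contacts=0)
    with pytest.raises(ValueError):
        ElectrodeArraySpec(pitch_m=0.1e-3, contact_length_m=0.4e-3)
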