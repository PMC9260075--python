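import numpy as np
import pytest

from scalasim.fem import ImpedanceRecord
from scalasim.geometry import Placement
from scalasim.protocols import (
    ImpedanceMap,
    config_hash,
    contact_label,
    contact_number,
    depth_rank_correlation,
    run_conductivity_sensitivity,
)


def test_contact_name_helpers():
    assert contact_label("E7") == "CONTACT_E7"
    assert contact_label("CONTACT_E7") == "CONTACT_E7"
    assert contact_number("CONTACT_E16") == 16
    assert contact_number("E3") == 3


def test_config_hash_stable_and_discriminating():
    h1 = config_hash({"a": 1, "b": [1, 2]})
    h2 = config_hash({"b": [1, 2], "a": 1})
    h3 = config_hash({"a": 2, "b": [1, 2]})
    assert h1 == h2
    assert h1 != h3
    assert len(h1) == 16


def test_impedance_map_rejects_duplicate_keys():
    imap = ImpedanceMap()
    rec = ImpedanceRecord(
        contact_id="CONTACT_E1",
        I_el_A=34e-6,
        V_el_V=0.034,
        Z_el_ohm=0.034 / 34e-6,
        placement=Placement(insertion_step=1),
    )
    imap.append(rec)
    with pytest.raises(ValueError):
        imap.append(rec)


def test_depth_profile_one_record_per_contact(depth_map, array):
    assert len(depth_map) == array.n_contacts
    labels = sorted(r.contact_id for r in depth_map.records)
    assert labels == sorted(f"CONTACT_E{i}" for i in range(1, 17))
    assert all(r.placement.insertion_step == 16 for r in depth_map.records)
    assert all(r.Z_el_ohm > 0 for r in depth_map.records)


def test_sequential_insertion_step_k_has_k_records(sequential_map):
    by_step = {}
    for r in sequential_map.records:
        by_step.setdefault(r.placement.insertion_step, []).append(r)
    assert sorted(by_step) == list(range(1, 17))
    for k, recs in by_step.items():
        labels = sorted(r.contact_id for r in recs)
        assert labels == sorted(f"CONTACT_E{i}" for i in range(1, k + 1))


def test_sequential_final_step_matches_depth_profile(sequential_map, depth_map):
    # the depth profile is exactly the k = 16 slice of the sequential protocol
    for r in depth_map.records:
        twin = sequential_map.record(None, 16, r.contact_id)
        assert twin.Z_el_ohm == pytest.approx(r.Z_el_ohm, rel=1e-12)


def test_depth_rank_correlation_range(depth_map):
    rho = depth_rank_correlation(depth_map)
    assert -1.0 <= rho <= 1.0


def test_proximity_sweep_records_only_selected_contacts(proximity_x_map):
    labels = {r.contact_id for r in proximity_x_map.records}
    assert labels == {"CONTACT_E1", "CONTACT_E16"}
    # all 12 x-axis candidates are valid, none skipped
    assert proximity_x_map.skipped == []
    assert len(proximity_x_map) == 24
    # placements stay on the x axis
    assert all(r.placement.y_offset_m == 0.0 for r in proximity_x_map.records)


def test_proximity_sweep_metadata_and_dataframe(proximity_x_map):
    assert "config_hash" in proximity_x_map.metadata
    df = proximity_x_map.to_dataframe()
    assert len(df) == len(proximity_x_map)
    assert {"contact_id", "x_offset_m", "Z_el_ohm"} <= set(df.columns)
    assert (df["Z_el_ohm"] > 0).all()


def test_sensitivity_result_structure(sensitivity_result):
    r = sensitivity_result
    assert r.layer == "scala_tympani"
    assert r.perturbation_factors == pytest.approx([0.90, 0.95, 1.0, 1.05, 1.10])
    assert r.positions_m[r.mid_index] == (0.0, 0.0)
    # each normalized profile is 1 at mid-scala by construction
    for f in r.perturbation_factors:
        assert r.normalized_profile(f)[r.mid_index] == pytest.approx(1.0)
    assert r.normalized_deviation >= 0
    assert r.absolute_shift > 0  # raw impedances do move with sigma


def test_sensitivity_requires_mid_scala_placement(params, array, cond):
    sweep = [Placement(x_offset_m=5e-5), Placement(x_offset_m=1e-4)]
    with pytest.raises(ValueError):
        run_conductivity_sensitivity(params, array, cond=cond, sweep=sweep)


def test_sensitivity_rejects_bad_step(params, array, cond):
    with pytest.raises(ValueError):
        run_conductivity_sensitivity(params, array, cond=cond, step=0.3, range_=0.1)
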