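"""Property-based tests of the pure numeric helpers (derandomized)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scalasim.conductivity import ConductivityTable
from scalasim.geometry import ellipse_perimeter, point_to_ellipse_distance
from scalasim.protocols import config_hash, contact_label, contact_number
from scalasim.validation import (
    bar_resistance,
    concentric_spheres_resistance,
    disk_spreading_resistance,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

positive = st.floats(
    min_value=1e-6, max_value=1e6, allow_nan=False, allow_infinity=False
)


@given(st.integers(min_value=1, max_value=10_000))
def test_contact_label_number_round_trip(i):
    assert contact_number(contact_label(f"E{i}")) == i
    assert contact_label(contact_label(f"E{i}")) == f"CONTACT_E{i}"


@given(
    st.dictionaries(
        st.text(min_size=1, max_size=8),
        st.one_of(st.integers(), st.floats(allow_nan=False), st.text(max_size=8)),
        min_size=1,
        max_size=6,
    )
)
def test_config_hash_is_order_invariant(d):
    items = list(d.items())
    shuffled = dict(reversed(items))
    assert config_hash(d) == config_hash(shuffled)


@given(sigma=positive, a=positive)
def test_disk_resistance_scaling(sigma, a):
    base = disk_spreading_resistance(sigma, a)
    assert base > 0
    # doubling sigma or the radius halves the spreading resistance
    assert disk_spreading_resistance(2 * sigma, a) == pytest.approx(base / 2)
    assert disk_spreading_resistance(sigma, 2 * a) == pytest.approx(base / 2)


@given(sigma=positive, length=positive, area=positive)
def test_bar_resistance_scaling(sigma, length, area):
    base = bar_resistance(sigma, length, area)
    assert bar_resistance(sigma, 2 * length, area) == pytest.approx(2 * base)
    assert bar_resistance(sigma, length, 2 * area) == pytest.approx(base / 2)


@given(sigma=positive, a=st.floats(min_value=1e-4, max_value=1e-2), k=st.floats(min_value=1.1, max_value=100.0))
def test_spheres_resistance_monotone_in_outer_radius(sigma, a, k):
    r1 = concentric_spheres_resistance(sigma, a, k * a)
    r2 = concentric_spheres_resistance(sigma, a, 2 * k * a)
    assert 0 < r1 < r2
    # the infinite-medium limit bounds every finite shell
    assert r2 < 1.0 / (4 * math.pi * sigma * a)


@given(factor=st.floats(min_value=0.01, max_value=100.0))
def test_conductivity_scaling_round_trip(factor):
    cond = ConductivityTable()
    scaled = cond.scaled(factor)
    for name, sigma in cond.sigma_S_per_m.items():
        assert scaled[name] == pytest.approx(sigma * factor)
    back = scaled.scaled(1.0 / factor)
    for name, sigma in cond.sigma_S_per_m.items():
        assert back[name] == pytest.approx(sigma)


@given(
    a=st.floats(min_value=0.5, max_value=10.0),
    ratio=st.floats(min_value=0.1, max_value=1.0),
    px=st.floats(min_value=-20.0, max_value=20.0),
    py=st.floats(min_value=-20.0, max_value=20.0),
)
def test_point_to_ellipse_distance_properties(a, ratio, px, py):
    b = a * ratio
    d = float(point_to_ellipse_distance(np.array([[px, py]]), a, b)[0])
    assert d >= 0
    # the distance never exceeds the distance to the nearest vertex
    nearest_vertex = min(
        math.hypot(px - sx * a, py) for sx in (-1, 1)
    )
    nearest_covertex = min(math.hypot(px, py - sy * b) for sy in (-1, 1))
    assert d <= min(nearest_vertex, nearest_covertex) + 1e-9 * max(1.0, a)


@given(a=st.floats(min_value=0.1, max_value=10.0), ratio=st.floats(min_value=0.05, max_value=1.0))
def test_ellipse_perimeter_bounds(a, ratio):
    b = a * ratio
    p = ellipse_perimeter(a, b)
    # classical bounds: pi*(a+b) <= P <= 2*pi*max(a,b) (ellipse vs circle)
    assert math.pi * (a + b) <= p * (1 + 1e-9)
    assert p <= 2 * math.pi * a * (1 + 1e-9)
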