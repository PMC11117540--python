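"""Geometric features: hand-computed cases, oracle agreement, equivariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import frfteeg.features as ft
from frfteeg import FEATURE_NAMES, extract_features

from oracles import bf_all_features

IDX = {name: i for i, name in enumerate(FEATURE_NAMES)}


# ---- hand-computed examples -------------------------------------------------

@pytest.mark.parametrize(
    "func,pts,expected",
    [
        (ft.consecutive_circle_area, [(0, 0), (2, 0)], math.pi),
        (ft.consecutive_circle_area, [(0, 0)], 0.0),
        (ft.consecutive_circle_area, [(0, 0), (2, 0), (2, 2)], 2 * math.pi),
        (ft.consecutive_triangle_area, [(0, 0), (1, 0), (2, 0)], 0.0),
        (ft.consecutive_triangle_area, [(0, 0), (1, 0), (0, 1)], 0.5),
        (ft.consecutive_triangle_area, [(0, 0), (1, 0), (0, 1), (1, 1)], 1.0),
        (ft.polyline_length, [(0, 0), (3, 4)], 5.0),
        (ft.polyline_length, [(0, 0)], 0.0),
        (ft.polyline_length, [(0, 0), (3, 4), (3, 4)], 5.0),
        (ft.radial_distance_sum, [(3, 4)], 5.0),
        (ft.radial_distance_sum, [(0, 0)], 0.0),
        (ft.radial_distance_sum, [(3, 4), (0, 5)], 10.0),
        (ft.turning_angle_sum, [(0, 0), (1, 0), (2, 0)], math.pi),
        (ft.turning_angle_sum, [(0, 0), (1, 0), (1, 1)], math.pi / 2),
        (ft.turning_angle_sum, [(0, 0), (1, 0)], 0.0),
        (ft.origin_triangle_area, [(1, 0), (0, 1)], 0.5),
        (ft.origin_triangle_area, [(1, 1), (2, 2)], 0.0),
        (ft.origin_triangle_area, [(1, 0)], 0.0),
        (ft.rectangle_area_sum, [(1, 0)], 0.5),
        (ft.rectangle_area_sum, [(1, 1)], 0.0),
        (ft.rectangle_area_sum, [(2, 0)], 2.0),
        (ft.octagon_area, [(1, 1), (1, -1), (-1, 1), (-1, -1)], 4.0),
        (ft.octagon_area, [(0.5, 0.5)], 0.0),
        (ft.ellipse_area, [(1, 0), (-1, 0), (0, 1), (0, -1)], 2 * math.pi / 3),
        (ft.ellipse_area, [(0, 0), (1, 1), (2, 2)], 0.0),
        (ft.ellipse_area, [(1, 1), (1, 1), (1, 1)], 0.0),
        (ft.poincare_dispersion, [(1, 0), (-1, 0), (0, 1), (0, -1)],
         2 * math.sqrt(2.0 / 3.0)),
        (ft.poincare_dispersion, [(2, 2), (2, 2)], 0.0),
        (ft.poincare_dispersion, [(1, 2)], 0.0),
    ],
)
def test_single_feature_examples(func, pts, expected):
    assert func(np.asarray(pts, dtype=float)) == pytest.approx(expected, abs=1e-12)


def test_octagon_of_octagonal_cloud():
    th = np.arange(8) * np.pi / 4
    pts = np.column_stack([np.cos(th), np.sin(th)])
    assert ft.octagon_area(pts) == pytest.approx(8 * math.tan(math.pi / 8))


def test_diagonal_distances():
    assert ft.diagonal_distance_sums([(1, 1), (2, 2)])[0] == pytest.approx(0.0)
    sh45, sh135 = ft.diagonal_distance_sums([(1, 0)])
    assert (sh45, sh135) == pytest.approx((1 / math.sqrt(2), 1 / math.sqrt(2)))
    assert ft.diagonal_distance_sums([(1, 0), (0, 1)])[0] == pytest.approx(math.sqrt(2))


def test_circumcircle_right_triangle():
    shca, sdhc, sahc = ft.circumcircle_features([(0, 0), (1, 0), (0, 1)])
    assert shca == pytest.approx(math.pi / 2)
    assert sdhc == 0.0 and sahc == 0.0


def test_circumcircle_collinear_cloud_all_degenerate():
    pts = np.column_stack([np.arange(6.0), np.arange(6.0)])
    assert ft.circumcircle_features(pts) == (0.0, 0.0, 0.0)


def test_circumcircle_shared_circle_zero_spacing():
    shca, sdhc, _ = ft.circumcircle_features([(0, 0), (1, 0), (0, 1), (1, 1)])
    assert sdhc == pytest.approx(0.0, abs=1e-12)
    assert shca == pytest.approx(math.pi)  # two circles of radius sqrt(2)/2


def test_ctm_counting_and_degenerate_cases():
    pts = [(float(i), 0.0) for i in range(1, 11)]
    ctm = ft.central_tendency_measures(pts)
    assert ctm[0] == 0.0 and ctm[1] == pytest.approx(0.1)
    assert ctm[18] == pytest.approx(0.9)
    # every point on a common circle: nothing strictly inside 0.95*r_max
    th = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    on_circle = np.column_stack([np.cos(th), np.sin(th)])
    assert np.all(ft.central_tendency_measures(on_circle) == 0.0)
    assert np.all(ft.central_tendency_measures([(0.0, 0.0)] * 5) == 1.0)


def test_zero_cloud_feature_vector():
    vec = extract_features(np.zeros((8, 2)))
    assert np.all(vec[:15] == 0.0)
    assert np.all(vec[15:] == 1.0)


def test_empty_cloud_rejected():
    with pytest.raises(ValueError, match="empty"):
        extract_features(np.empty((0, 2)))


# ---- oracle agreement and invariances --------------------------------------

def test_all_features_match_bruteforce_oracle():
    for seed in range(30):
        pts = np.random.default_rng(seed).normal(scale=2.0, size=(50, 2))
        got = extract_features(pts)
        want = bf_all_features(pts)
        rel = np.abs(got - want) / np.maximum(np.abs(want), 1e-30)
        assert rel.max() <= 1e-9, FEATURE_NAMES[int(rel.argmax())]


def test_scale_equivariance(rng):
    pts = rng.normal(size=(40, 2))
    s = 3.7
    base = extract_features(pts)
    scaled = extract_features(s * pts)
    for name, i in IDX.items():
        expected = base[i] * s ** ft.SCALE_DEGREE[name]
        assert scaled[i] == pytest.approx(expected, rel=1e-9, abs=1e-12), name


def test_rotation_invariance_of_radial_features(rng):
    pts = rng.normal(size=(40, 2))
    th = 1.1
    rot = pts @ np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
    a, b = extract_features(pts), extract_features(rot)
    for name in ("SSVL", "SDTC", "SATP", "ELPA") + tuple(
        f"CTM{i}" for i in range(1, 20)
    ):
        assert b[IDX[name]] == pytest.approx(a[IDX[name]], rel=1e-9), name


def test_permutation_changes_order_features_only(rng):
    pts = rng.normal(size=(30, 2))
    perm = rng.permutation(30)
    a, b = extract_features(pts), extract_features(pts[perm])
    for name in ("SH45", "SH135", "AOCT", "SDTC", "SCRA", "TDSD", "ELPA") + tuple(
        f"CTM{i}" for i in range(1, 20)
    ):
        assert b[IDX[name]] == pytest.approx(a[IDX[name]], rel=1e-9), name
    # at least one order-dependent feature must move for a generic cloud
    order_dep = [IDX[n] for n in ("SCCA", "SCTA", "SSVL", "SATP", "TACR")]
    assert not np.allclose(a[order_dep], b[order_dep])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    arrays(
        float,
        st.tuples(st.integers(2, 25), st.just(2)),
        elements=st.floats(-100, 100, allow_nan=False),
    )
)
def test_ctm_bounds_and_monotonicity(pts):
    ctm = ft.central_tendency_measures(pts)
    assert np.all(ctm >= 0.0) and np.all(ctm <= 1.0)
    assert np.all(np.diff(ctm) >= 0.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    arrays(
        float,
        st.tuples(st.integers(1, 20), st.just(2)),
        elements=st.floats(-50, 50, allow_nan=False),
    )
)
def test_feature_vector_is_finite_and_well_shaped(pts):
    vec = extract_features(pts)
    assert vec.shape == (34,)
    assert np.isfinite(vec).all()
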