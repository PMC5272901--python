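"""Geometry of the shape primitives and their pairwise contacts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import oracles
from conftest import random_shape, random_spheroid, random_tube
from hiersim.shapes import (Contact, Sphere, Spheroid, Tube,
                            contact_spheroid_spheroid, focal_half_distance,
                            gap_sphere_sphere, gap_sphere_spheroid,
                            gap_sphere_tube, gap_tube_spheroid, gap_tube_tube,
                            in_egg, radial_project, spheroid_contact_search,
                            touch, vec_to_egg)


# ---------------------------------------------------------------------------
# frozen trivial cases

@pytest.mark.parametrize("a,b,expected", [
    (Sphere([0, 0, 0], 1), Sphere([3, 0, 0], 1), 1.0),
    (Sphere([0, 0, 0], 2), Sphere([3, 0, 0], 1), 0.0),
    (Sphere([0, 0, 0], 1), Sphere([0, 0, 0], 1), -2.0),
    # sphere at perpendicular distance 3 from mid-axis of a unit tube
    (Sphere([0, 3, 0], 1), Tube([-2, 0, 0], [2, 0, 0], 1), 1.0),
    # sphere 3 beyond the near cap centre, on-axis: cap reduces to sphere
    (Sphere([5, 0, 0], 1), Tube([-2, 0, 0], [2, 0, 0], 1), 1.0),
    # parallel tubes, axes 3 apart, overlapping spans
    (Tube([-1, 0, 0], [1, 0, 0], 1), Tube([-1, 3, 0], [1, 3, 0], 1), 1.0),
    # perpendicular skew axes, common perpendicular 2
    (Tube([-1, 0, 0], [1, 0, 0], 0.5), Tube([0, -1, 2], [0, 1, 2], 0.5), 1.0),
    # unit sphere at 3 along the major axis of a prolate a=2,b=1: touching
    (Sphere([0, 0, 3], 1), Spheroid([0, 0, 0], [0, 0, 1], 2, 1), 0.0),
    # zero-ish tube against a prolate pole
    (Tube([0, 0, 4], [0, 0, 6], 0.5), Spheroid([0, 0, 0], [0, 0, 1], 2, 1), 1.5),
])
def test_touch_frozen_cases(a, b, expected):
    assert touch(a, b).gap == pytest.approx(expected, abs=1e-9)


def test_touch_rejects_unknown_kind():
    with pytest.raises(TypeError):
        touch(Sphere([0, 0, 0], 1), object())


def test_coincident_spheres_tie_break_is_deterministic():
    c1 = touch(Sphere([1, 2, 3], 1), Sphere([1, 2, 3], 1))
    c2 = touch(Sphere([1, 2, 3], 1), Sphere([1, 2, 3], 1))
    assert np.allclose(c1.normal, c2.normal)
    assert np.allclose(c1.normal, [1, 0, 0])


# ---------------------------------------------------------------------------
# spheroid utilities

def test_focal_half_distance_values():
    assert focal_half_distance(Spheroid([0]*3, [0, 0, 1], 5, 3)) == pytest.approx(4)
    assert focal_half_distance(Spheroid([0]*3, [0, 0, 1], 2, 2)) == 0.0


def test_focal_identity_b2_plus_c2_equals_a2(rng):
    for _ in range(100):
        e = random_spheroid(rng)
        c = focal_half_distance(e)
        major = max(e.semi_axial, e.semi_transverse)
        minor = min(e.semi_axial, e.semi_transverse)
        assert minor ** 2 + c ** 2 == pytest.approx(major ** 2, abs=1e-12)


def test_in_egg_zero_on_surface(rng):
    for _ in range(50):
        e = random_spheroid(rng)
        th, ph = rng.uniform(0, math.pi), rng.uniform(0, 2 * math.pi)
        p = oracles.spheroid_surface(e, th, ph)
        assert in_egg(p, e) == pytest.approx(0.0, abs=1e-9)


def test_in_egg_sign_matches_implicit_equation(rng):
    for _ in range(1000):
        e = random_spheroid(rng)
        p = e.center + rng.normal(scale=2.0, size=3)
        implicit = e.implicit(p)
        if abs(implicit) < 1e-9:
            continue
        assert np.sign(in_egg(p, e)) == np.sign(implicit)


def test_in_egg_sphere_limit_sign():
    e = Spheroid([0, 0, 0], [0, 0, 1], 1.5, 1.5)
    for d in (0.3, 1.0, 1.4999, 1.5001, 4.0):
        assert np.sign(in_egg([d, 0, 0], e)) == np.sign(d - 1.5)


def test_vec_to_egg_exact_cases():
    prolate = Spheroid([0, 0, 0], [0, 0, 1], 2, 1)
    d, foot = vec_to_egg([0, 0, 3], prolate)
    assert d == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(foot, [0, 0, 2], atol=1e-12)
    ball = Spheroid([1, 1, 1], [0, 1, 0], 1.5, 1.5)
    d, _ = vec_to_egg([1, 1, 4], ball)
    assert d == pytest.approx(1.5, abs=1e-12)
    d, foot = vec_to_egg([1, 1, 1], ball)   # centre: tie-break
    assert d == pytest.approx(-1.5, abs=1e-12)


def test_vec_to_egg_against_sampling_oracle(rng):
    for _ in range(40):
        e = random_spheroid(rng)
        p = e.center + rng.normal(scale=2.5, size=3)
        d, foot = vec_to_egg(p, e)
        od = oracles.oracle_point_spheroid(p, e)
        assert d == pytest.approx(od, abs=1e-4)
        assert abs(np.linalg.norm(foot - p)) == pytest.approx(abs(d), abs=1e-9)
        assert e.implicit(foot) == pytest.approx(0.0, abs=1e-7)


def test_vec_to_egg_in_egg_signs_agree(rng):
    for _ in range(300):
        e = random_spheroid(rng)
        p = e.center + rng.normal(scale=2.0, size=3)
        d, _ = vec_to_egg(p, e)
        if abs(d) < 1e-9:
            continue
        assert np.sign(d) == np.sign(in_egg(p, e))


def test_radial_project_residual_and_cases(rng):
    e = Spheroid([0, 0, 0], [0, 0, 1], 2, 1)
    assert np.allclose(radial_project([0, 0, 9], e), [0, 0, 2])
    ball = Spheroid([1, 0, 0], [0, 0, 1], 2, 2)
    p = np.array([3.0, 2.0, -1.0])
    proj = radial_project(p, ball)
    assert np.linalg.norm(proj - ball.center) == pytest.approx(2.0, abs=1e-12)
    for _ in range(100):
        e = random_spheroid(rng)
        p = e.center + rng.normal(scale=2.0, size=3)
        if np.linalg.norm(p - e.center) < 1e-6:
            continue
        assert e.implicit(radial_project(p, e)) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        radial_project(e.center, e)


# ---------------------------------------------------------------------------
# oracle agreement for every pair routine

def _routine_oracle_pairs(rng, kind, n):
    for _ in range(n):
        if kind == "sphere_sphere":
            a = Sphere(rng.uniform(-3, 3, 3), rng.uniform(0.3, 2))
            b = Sphere(rng.uniform(-3, 3, 3), rng.uniform(0.3, 2))
            got = gap_sphere_sphere(a, b).gap
            want = float(np.linalg.norm(b.center - a.center)) - a.radius - b.radius
        elif kind == "sphere_tube":
            a = Sphere(rng.uniform(-3, 3, 3), rng.uniform(0.3, 2))
            b = random_tube(rng)
            got = gap_sphere_tube(a, b).gap
            want = oracles.oracle_gap_sphere_tube(a, b)
        elif kind == "tube_tube":
            a, b = random_tube(rng), random_tube(rng)
            got = gap_tube_tube(a, b).gap
            want = oracles.oracle_gap_tube_tube(a, b)
        elif kind == "sphere_spheroid":
            a = Sphere(rng.uniform(-4, 4, 3), rng.uniform(0.3, 2))
            b = random_spheroid(rng)
            got = gap_sphere_spheroid(a, b).gap
            want = oracles.oracle_gap_sphere_spheroid(a, b)
        elif kind == "tube_spheroid":
            a, b = random_tube(rng), random_spheroid(rng)
            c = gap_tube_spheroid(a, b)
            if c.gap <= 0.02:     # surface-distance oracle needs disjoint pairs
                continue
            got = c.gap
            want = oracles.oracle_gap_tube_spheroid(a, b)
        else:
            a = random_spheroid(rng)
            b = random_spheroid(rng, center_scale=5.0)
            c = contact_spheroid_spheroid(a, b)
            if c.gap <= 0.02:     # oracle is only sharp for disjoint pairs
                continue
            got = c.gap
            want = oracles.oracle_gap_spheroid_spheroid(a, b)
        yield got, want


@pytest.mark.parametrize("kind", ["sphere_sphere", "sphere_tube", "tube_tube",
                                  "sphere_spheroid", "tube_spheroid",
                                  "spheroid_spheroid"])
def test_gap_routines_match_independent_oracles(kind, rng):
    n = 100 if kind in ("sphere_sphere", "sphere_tube") else 30
    for got, want in _routine_oracle_pairs(rng, kind, n):
        scale = max(abs(want), 1e-3)
        assert abs(got - want) / scale < 1e-3, (kind, got, want)


def test_sign_correctness_against_sampling(rng):
    kinds = ["sphere", "tube", "spheroid"]
    for _ in range(150):
        a = random_shape(rng, rng.choice(kinds), center_scale=1.5)
        b = random_shape(rng, rng.choice(kinds), center_scale=1.5)
        gap = touch(a, b).gap
        if abs(gap) < 2e-2:
            continue          # too close to the surface for a sampling oracle
        overlap = oracles.overlap_by_sampling(a, b, rng)
        assert (gap < 0) == overlap, (type(a).__name__, type(b).__name__, gap)


# ---------------------------------------------------------------------------
# invariants

def test_touch_symmetry(rng):
    for _ in range(60):
        a = random_shape(rng)
        b = random_shape(rng)
        ca, cb = touch(a, b), touch(b, a)
        assert ca.gap == pytest.approx(cb.gap, abs=1e-9)
        assert np.allclose(ca.normal, -cb.normal, atol=1e-6) or ca.gap < 0


def test_sphere_limit_consistency(rng):
    for _ in range(40):
        s = Sphere(rng.uniform(-3, 3, 3), rng.uniform(0.3, 1.5))
        c = rng.uniform(-3, 3, 3)
        r = rng.uniform(0.4, 1.8)
        ref = gap_sphere_sphere(s, Sphere(c, r)).gap
        degenerate_tube = Tube(c, c, r)
        ax = rng.normal(size=3)
        ax /= np.linalg.norm(ax)
        degenerate_egg = Spheroid(c, ax, r, r)
        assert gap_sphere_tube(s, degenerate_tube).gap == pytest.approx(ref, abs=1e-6)
        assert gap_sphere_spheroid(s, degenerate_egg).gap == pytest.approx(ref, abs=1e-6)


def test_spheroid_pair_sphere_limit_matches_sphere_contact(rng):
    for _ in range(20):
        c1, c2 = rng.uniform(-3, 3, (2, 3))
        r1, r2 = rng.uniform(0.4, 1.5, 2)
        ax = rng.normal(size=3)
        ax /= np.linalg.norm(ax)
        ref = gap_sphere_sphere(Sphere(c1, r1), Sphere(c2, r2))
        got = contact_spheroid_spheroid(Spheroid(c1, ax, r1, r1),
                                        Spheroid(c2, ax, r2, r2))
        assert got.gap == pytest.approx(ref.gap, abs=1e-6)


def test_rigid_motion_invariance(rng):
    for _ in range(40):
        a = random_shape(rng)
        b = random_shape(rng)
        g0 = touch(a, b).gap
        rot = Rotation.random(rng=rng).as_matrix()
        about = rng.uniform(-2, 2, 3)
        d = rng.uniform(-5, 5, 3)
        for s in (a, b):
            s.transform(rot, about)
            s.translate(d)
        assert touch(a, b).gap == pytest.approx(g0, abs=1e-9)


def test_contact_points_consistent_with_gap(rng):
    for _ in range(60):
        a = random_shape(rng)
        b = random_shape(rng)
        c = touch(a, b)
        if c.gap > 0:
            assert np.linalg.norm(c.point_a - c.point_b) == pytest.approx(
                c.gap, rel=1e-6)
        assert np.linalg.norm(c.normal) == pytest.approx(1.0, abs=1e-9)


def test_spheroid_search_validation_typically_small(rng):
    """The raw quad-section search self-check (exact distance from each
    candidate contact point to the opposing surface) typically agrees to
    well under a percent on disjoint pairs."""
    discs = []
    while len(discs) < 40:
        e1 = random_spheroid(rng)
        e2 = random_spheroid(rng, center_scale=5.0)
        if contact_spheroid_spheroid(e1, e2).gap <= 0.05:
            continue
        discs.append(spheroid_contact_search(e1, e2)[2])
    assert np.median(discs) < 1e-3


# ---------------------------------------------------------------------------
# property-based checks

@settings(derandomize=True, max_examples=60, deadline=None)
@given(a=st.floats(0.3, 4.0), b=st.floats(0.3, 4.0),
       z=st.floats(-6.0, 6.0), u=st.floats(0.0, 6.0))
def test_vec_to_egg_sign_matches_implicit(a, b, z, u):
    e = Spheroid([0, 0, 0], [0, 0, 1], a, b)
    p = np.array([u, 0.0, z])
    implicit = e.implicit(p)
    if abs(implicit) < 1e-6:
        return
    d, _ = vec_to_egg(p, e)
    assert np.sign(d) == np.sign(implicit)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(r1=st.floats(0.3, 2.0), r2=st.floats(0.3, 2.0),
       dx=st.floats(0.0, 8.0))
def test_sphere_gap_closed_form(r1, r2, dx):
    got = gap_sphere_sphere(Sphere([0, 0, 0], r1), Sphere([dx, 0, 0], r2)).gap
    assert got == pytest.approx(dx - r1 - r2, abs=1e-12)
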