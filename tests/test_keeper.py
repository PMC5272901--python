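"""Containment corrections: margins, keep-sign semantics, duplex basepairs."""

import numpy as np
import pytest

from hiersim import constants
from hiersim.hierarchy import Node, ParamRecord, ParamSet, leaves
from hiersim.keeper import (KeepPolicy, apply_keeper, pack_ball, pack_base,
                            pack_egg, pack_tube)
from hiersim.shapes import Sphere, Spheroid, Tube, in_egg


def child_at(p, r=0.5, level=1, kind="generic"):
    return Node(Sphere(p, r), level=level, kind=kind)


def test_pack_ball_margin_band_and_step():
    parent = Node(Sphere([0, 0, 0], 5.0), level=0)
    pol = KeepPolicy(0.3, "inside")
    centre = parent.add_child(child_at([0, 0, 0]))
    pack_ball(parent, centre, pol)
    assert np.allclose(centre.center, [0, 0, 0])
    # effective radius 4.5; 1.05x is inside the +/-10% band
    banded = parent.add_child(child_at([4.5 * 1.05, 0, 0]))
    pack_ball(parent, banded, pol)
    assert np.allclose(banded.center, [4.5 * 1.05, 0, 0])
    outside = parent.add_child(child_at([9.0, 0, 0]))
    pack_ball(parent, outside, pol)
    assert np.allclose(outside.center, [8.7, 0, 0])


def test_pack_ball_on_surface_mode_pulls_outward():
    parent = Node(Sphere([0, 0, 0], 5.0), level=0)
    pol = KeepPolicy(0.3, "on_surface")
    inner = parent.add_child(child_at([1.0, 0, 0]))
    pack_ball(parent, inner, pol)
    assert inner.center[0] == pytest.approx(1.3)


def test_pack_ball_elongated_child_uses_transverse_radius():
    parent = Node(Sphere([0, 0, 0], 5.0), level=0)
    # prolate child: semi_axial 2 sticks out, semi_transverse 0.5 counts
    kid = parent.add_child(Node(Spheroid([9, 0, 0], [1, 0, 0], 2.0, 0.5),
                                level=1))
    pack_ball(parent, kid, KeepPolicy(0.3, "inside"))
    # effective radius 4.5, distance 9 -> moved inward by the step
    assert kid.shape.center[0] == pytest.approx(8.7)


def test_pack_tube_surface_and_inward():
    parent = Node(Tube([-5, 0, 0], [5, 0, 0], 2.0), level=0, kind="sse_alpha")
    pol = KeepPolicy(0.4, "on_surface")
    on_surface = parent.add_child(child_at([0, 2.0, 0]))
    pack_tube(parent, on_surface, pol)
    assert np.allclose(on_surface.center, [0, 2.0, 0])
    # helix residue at half the radius is pushed outward
    inner = parent.add_child(child_at([0, 1.0, 0]))
    pack_tube(parent, inner, pol)
    assert inner.center[1] == pytest.approx(1.4)
    outer = parent.add_child(child_at([0, 4.0, 0]))
    pack_tube(parent, outer, pol)
    assert outer.center[1] == pytest.approx(3.6)


def test_pack_tube_beyond_span_uses_end_cap():
    parent = Node(Tube([-5, 0, 0], [5, 0, 0], 2.0), level=0)
    pol = KeepPolicy(0.4, "on_surface")
    beyond = parent.add_child(child_at([9.0, 0, 0]))
    pack_tube(parent, beyond, pol)
    # nearest end-point (5,0,0) as sphere centre, distance 4 -> inward
    assert beyond.center[0] == pytest.approx(8.6)


def test_pack_tube_loop_children_weak_inside_only():
    parent = Node(Tube([-5, 0, 0], [5, 0, 0], 2.0), level=0, kind="sse_loop")
    pol = KeepPolicy(0.4, "on_surface")
    inside = parent.add_child(child_at([0, 1.0, 0]))
    pack_tube(parent, inside, pol, loop=True)
    assert np.allclose(inside.center, [0, 1.0, 0])    # inside: unmoved
    outside = parent.add_child(child_at([0, 5.0, 0]))
    pack_tube(parent, outside, pol, loop=True)
    # inside-only with a tenth of the step
    assert outside.center[1] == pytest.approx(5.0 - 0.04)
    past_cap = parent.add_child(child_at([9.0, 0, 0]))
    pack_tube(parent, past_cap, pol, loop=True)
    assert np.allclose(past_cap.center, [9.0, 0, 0])  # caps not enforced


def test_pack_egg_inside_mode_and_weighted_direction():
    parent = Node(Spheroid([0, 0, 0], [0, 0, 1], 5.0, 3.0), level=0)
    pol = KeepPolicy(0.3, "inside")
    centre = parent.add_child(child_at([0, 0, 0], r=0.4))
    pack_egg(parent, centre, pol)
    assert np.allclose(centre.center, [0, 0, 0])
    # child outside near the +z focus: displacement mostly toward it
    outside = parent.add_child(child_at([0.5, 0, 7.0], r=0.4))
    before = outside.center.copy()
    pack_egg(parent, outside, pol)
    d = outside.center - before
    assert np.linalg.norm(d) == pytest.approx(0.3, rel=1e-6)
    assert d[2] < 0                                  # pulled back inside
    f1 = np.array([0, 0, +4.0])                      # foci of a=5,b=3 ellipse
    f2 = np.array([0, 0, -4.0])
    u1 = (f1 - before) / np.linalg.norm(f1 - before)
    u2 = (f2 - before) / np.linalg.norm(f2 - before)
    assert np.dot(d, u1) > np.dot(d, u2)             # near focus dominates


def test_pack_egg_sphere_limit_matches_ball_direction():
    ball = Node(Sphere([0, 0, 0], 5.0), level=0)
    egg = Node(Spheroid([0, 0, 0], [0, 0, 1], 5.0, 5.0), level=0)
    pol = KeepPolicy(0.3, "inside")
    p = [4.0, 3.0, 2.0]
    cb = ball.add_child(child_at(p, r=0.4))
    ce = egg.add_child(child_at(p, r=0.4))
    pack_ball(ball, cb, pol)
    pack_egg(egg, ce, pol)
    db = cb.center - np.array(p)
    de = ce.center - np.array(p)
    cos = np.dot(db, de) / (np.linalg.norm(db) * np.linalg.norm(de))
    assert cos == pytest.approx(1.0, abs=1e-9)


def _duplex(n_pairs=4, span=None, rise=None, twist=None):
    ideal = constants.RNA_DUPLEX
    span = span or ideal.pp_span
    rise = rise or ideal.rise
    twist = ideal.twist if twist is None else twist
    stem = Node(Tube([0, 0, -0.5], [0, 0, n_pairs * rise + 0.5],
                     span / 2.0), level=1, kind="stemloop")
    for k in range(n_pairs):
        th = k * twist
        u = np.array([np.cos(th), np.sin(th), 0.0])
        p1 = 0.5 * span * u + [0, 0, k * rise]
        p2 = -0.5 * span * u + [0, 0, k * rise]
        bp = Node(Tube(p1, p2, 0.3), level=2, kind="basepair")
        bp.add_child(child_at(p1, r=0.5, level=3, kind="rna_phosphate"))
        bp.add_child(child_at(p2, r=0.5, level=3, kind="rna_phosphate"))
        stem.add_child(bp)
    return stem


def test_pack_base_ideal_geometry_unmoved():
    stem = _duplex()
    before = np.array([n.center for n in leaves(stem)])
    pol = KeepPolicy(0.1, "on_surface")
    prev = None
    for bp in stem.children:
        pack_base(stem, bp, pol, prev_base=prev)
        prev = bp
    after = np.array([n.center for n in leaves(stem)])
    assert np.abs(after - before).max() < 1e-9


def test_pack_base_refines_pp_span():
    stem = _duplex()
    bp = stem.children[0]
    p1, p2 = bp.children
    stretch = 1.1 * constants.RNA_DUPLEX.pp_span
    d = (p2.center - p1.center)
    d /= np.linalg.norm(d)
    p2.shape.set_center(p1.center + stretch * d)
    pol = KeepPolicy(0.1, "on_surface")
    pack_base(stem, bp, pol)
    got = np.linalg.norm(p2.center - p1.center)
    assert got < stretch
    assert np.allclose(bp.shape.end_a, p1.center)
    assert np.allclose(bp.shape.end_b, p2.center)


def test_pack_base_torsion_restores_right_hand():
    ideal = constants.RNA_DUPLEX
    left = _duplex(twist=-ideal.twist)       # mirrored, left-handed
    pol = KeepPolicy(0.05, "on_surface")

    def mean_twist(stem):
        ts = []
        axis = np.array([0, 0, 1.0])
        for a, b in zip(stem.children, stem.children[1:]):
            va = a.children[1].center - a.children[0].center
            vb = b.children[1].center - b.children[0].center
            va -= np.dot(va, axis) * axis
            vb -= np.dot(vb, axis) * axis
            va /= np.linalg.norm(va)
            vb /= np.linalg.norm(vb)
            ts.append(np.arctan2(np.dot(np.cross(va, vb), axis),
                                 np.dot(va, vb)))
        return np.mean(ts)

    t0 = mean_twist(left)
    assert t0 < 0
    for _ in range(40):
        prev = None
        for bp in left.children:
            pack_base(left, bp, pol, prev_base=prev)
            prev = bp
    t1 = mean_twist(left)
    assert t1 > t0          # torsion correction drives toward right-handed


def test_pack_base_requires_two_phosphates():
    stem = _duplex()
    bad = Node(Tube([0, 0, 0], [1, 0, 0], 0.3), level=2, kind="basepair")
    with pytest.raises(ValueError):
        pack_base(stem, bad, KeepPolicy(0.1, "on_surface"))


def test_keeper_idempotent_within_margins(rng):
    root = Node(Sphere([0, 0, 0], 6.0), level=0)
    for _ in range(6):
        p = rng.normal(size=3)
        p *= rng.uniform(0, 4.0) / np.linalg.norm(p)
        root.add_child(child_at(p, r=0.5))
    params = ParamSet({0: ParamRecord(keep=0.3)})
    snap = np.array([c.center for c in root.children])
    apply_keeper(root, params)
    assert np.allclose(snap, np.array([c.center for c in root.children]))


def test_keeper_monotone_containment():
    root = Node(Sphere([0, 0, 0], 4.0), level=0)
    stray = root.add_child(child_at([9.0, 0, 0], r=0.5))
    params = ParamSet({0: ParamRecord(keep=0.25)})
    excesses = []
    for _ in range(30):
        apply_keeper(root, params)
        excesses.append(max(0.0, np.linalg.norm(stray.center) - 3.5 * 1.1))
    assert all(b <= a + 1e-12 for a, b in zip(excesses, excesses[1:]))
    assert excesses[-1] == 0.0


def test_keeper_displaces_whole_subtree():
    root = Node(Sphere([0, 0, 0], 4.0), level=0)
    mid = root.add_child(Node(Sphere([8.0, 0, 0], 1.0), level=1))
    grand = mid.add_child(child_at([8.5, 0, 0], r=0.3, level=2))
    apply_keeper(root, ParamSet({0: ParamRecord(keep=0.5)}))
    assert mid.center[0] == pytest.approx(7.5)
    assert grand.center[0] == pytest.approx(8.0)    # moved with its parent


def test_keep_sign_reverses_tube_roles():
    root = Node(Tube([-5, 0, 0], [5, 0, 0], 2.0), level=0)
    inner = root.add_child(child_at([0, 1.0, 0], r=0.4))
    # keep > 0: tube children on the surface -> pushed outward
    apply_keeper(root, ParamSet({0: ParamRecord(keep=0.3)}))
    assert inner.center[1] == pytest.approx(1.3)
    # keep < 0: inside mode leaves interior children unmoved
    inner.shape.set_center([0, 1.0, 0])
    apply_keeper(root, ParamSet({0: ParamRecord(keep=-0.3)}))
    assert np.allclose(inner.center, [0, 1.0, 0])
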