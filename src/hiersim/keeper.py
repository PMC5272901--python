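"""Confine children inside (or on) their parent container's surface.

Straying children are returned by fixed-size corrective kicks whose size is
the per-level ``keep`` parameter.  The *sign* of ``keep`` selects the
behaviour: positive confines children within spheres and spheroids but on
the surface of a tube (the natural choice for secondary structures and
duplex nucleic acids); negative reverses the roles.  A +/-10% margin band
around the target surface suppresses action on children that are nearly in
place, saving recursive subtree moves and preventing in/out flutter.

Exceptions mirror the molecular conventions: children of loop-region tubes
are only held inside, with a tenth of the weight and no end-cap
enforcement; basepair tubes in a duplex are not themselves confined to the
duplex surface -- their phosphates are, via a skipped-generation call --
and the basepair geometry (P-P span, axis, helical twist sign) is refined
in the same pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants
from .hierarchy import Node, ParamSet, iter_nodes, move_node, rotate_node
from .shapes import (Sphere, Spheroid, Tube, _any_perpendicular, _unit,
                     focal_half_distance, in_egg, TIE_BREAK)

__all__ = ["KeepPolicy", "pack_ball", "pack_tube", "pack_egg", "pack_base",
           "apply_keeper"]


@dataclass
class KeepPolicy:
    step: float                  # |keep|
    mode: str                    # "inside" | "on_surface"
    margin_in: float = 0.9
    margin_out: float = 1.1


def _transverse_radius(n: Node) -> float:
    """Radius normal to the symmetry axis: the ends of tubes and prolate
    spheroids may stick out of their container."""
    s = n.shape
    if isinstance(s, Sphere):
        return s.radius
    if isinstance(s, Tube):
        return s.radius
    return s.semi_transverse


def _radial_correction(child: Node, center: np.ndarray, target: float,
                       policy: KeepPolicy, axis_hint=None) -> None:
    """Shared sphere-like correction toward distance ``target`` from a
    fixed centre (used for spheres and tube end-caps)."""
    d = child.center - center
    dist = float(np.linalg.norm(d))
    if dist < 1e-12:
        direction = _any_perpendicular(axis_hint) if axis_hint is not None \
            else TIE_BREAK.copy()
    else:
        direction = d / dist
    if dist > target * policy.margin_out:
        mv = min(policy.step, dist - target)
        move_node(child, -mv * direction)
    elif policy.mode == "on_surface" and dist < target * policy.margin_in:
        mv = min(policy.step, target - dist)
        move_node(child, mv * direction)


def pack_ball(parent: Node, child: Node, policy: KeepPolicy) -> None:
    """Keep a child inside (or on) a spherical parent.

    The effective radius subtracts the child's transverse radius so the full
    child body stays inside; no action within the margin band.
    """
    eff = max(1e-9, parent.shape.radius - _transverse_radius(child))
    _radial_correction(child, parent.shape.center, eff, policy)


def pack_tube(parent: Node, child: Node, policy: KeepPolicy,
              loop: bool = False) -> None:
    """Keep a child on (or inside) the surface of a tube parent.

    Within the axial span the correction is along the perpendicular to the
    axis; beyond it, the nearest end-point is treated as a sphere centre.
    Loop-region children are special-cased: inside only, a tenth of the
    step, and no end-cap enforcement.
    """
    t: Tube = parent.shape
    if loop:
        policy = KeepPolicy(policy.step / 10.0, "inside",
                            policy.margin_in, policy.margin_out)
    if policy.mode == "on_surface":
        target = t.radius
    else:
        target = max(1e-9, t.radius - _transverse_radius(child))
    ab = t.end_b - t.end_a
    denom = float(np.dot(ab, ab))
    s = float(np.dot(child.center - t.end_a, ab)) / denom if denom > 1e-300 else 0.5
    if 0.0 <= s <= 1.0 or denom <= 1e-300:
        foot = t.end_a + min(1.0, max(0.0, s)) * ab
        d = child.center - foot
        rho = float(np.linalg.norm(d))
        direction = d / rho if rho > 1e-12 else _any_perpendicular(t.axis)
        if rho > target * policy.margin_out:
            mv = min(policy.step, rho - target)
            move_node(child, -mv * direction)
        elif policy.mode == "on_surface" and rho < target * policy.margin_in:
            mv = min(policy.step, target - rho)
            move_node(child, mv * direction)
    elif not loop:
        end = t.end_a if s < 0.0 else t.end_b
        _radial_correction(child, end, target, policy, axis_hint=t.axis)


def _foci_3d(e: Spheroid, toward: np.ndarray):
    """The two foci of the meridional ellipse through ``toward``, in 3-D.

    Prolate spheroids have true foci on the axis; for oblate ones the focal
    ring is represented by its nearest and farthest points in the child's
    meridional half-plane.
    """
    c = focal_half_distance(e)
    if e.semi_axial >= e.semi_transverse:
        return e.center + c * e.axis, e.center - c * e.axis
    u, v, rdir = e.meridional(toward)
    return e.center + c * rdir, e.center - c * rdir


def pack_egg(parent: Node, child: Node, policy: KeepPolicy) -> None:
    """Keep a child inside (or on) a spheroid parent.

    Out-of-bounds is decided by the cheap focal-sum test on the effective
    (child-radius shrunken, margin-scaled) spheroid; the correction is
    directed along the inverse-distance weighted combination of the unit
    vectors toward the two foci, so a child that strayed near one focus is
    pulled mostly toward that focus.
    """
    e: Spheroid = parent.shape
    rc = _transverse_radius(child)
    a_eff = max(1e-9, e.semi_axial - rc)
    b_eff = max(1e-9, e.semi_transverse - rc)
    outer = Spheroid(e.center, e.axis, a_eff * policy.margin_out,
                     b_eff * policy.margin_out)
    eff = Spheroid(e.center, e.axis, a_eff, b_eff)

    f1, f2 = _foci_3d(eff, child.center)
    d1 = float(np.linalg.norm(f1 - child.center))
    d2 = float(np.linalg.norm(f2 - child.center))
    if d1 < 1e-12:
        direction = _unit(f2 - child.center, fallback=TIE_BREAK)
    elif d2 < 1e-12:
        direction = _unit(f1 - child.center, fallback=TIE_BREAK)
    else:
        u1 = (f1 - child.center) / d1
        u2 = (f2 - child.center) / d2
        direction = _unit(u1 / d1 + u2 / d2, fallback=TIE_BREAK)

    excess = in_egg(child.center, outer)
    if excess > 0.0:
        mv = min(policy.step, excess)
        move_node(child, mv * direction)
    elif policy.mode == "on_surface":
        inner = Spheroid(e.center, e.axis, a_eff * policy.margin_in,
                         b_eff * policy.margin_in)
        deficit = in_egg(child.center, inner)
        if deficit < 0.0:
            mv = min(policy.step, -deficit)
            move_node(child, -mv * direction)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.from_rotvec(angle * axis).as_matrix()


def pack_base(grandparent: Node, base: Node, policy: KeepPolicy,
              prev_base: Node | None = None,
              ideal: constants.DuplexIdeal | None = None) -> None:
    """Duplex basepair containment with a skipped generation.

    The two phosphates (not the basepair tube) are pushed toward the duplex
    tube surface; the P-P span across the pair is refined toward its ideal;
    the basepair tube's axis end-points are reset to the phosphates; and the
    torsion about the duplex axis relative to the preceding basepair is
    refined toward the ideal right-handed twist.
    """
    if len(base.children) != 2:
        raise ValueError("a basepair node must have exactly 2 phosphate children")
    if ideal is None:
        ideal = constants.RNA_DUPLEX
    p1, p2 = base.children
    on_surface = KeepPolicy(policy.step, "on_surface",
                            policy.margin_in, policy.margin_out)
    pack_tube(grandparent, p1, on_surface)
    pack_tube(grandparent, p2, on_surface)

    # refine the P-P span across the pair
    d = p2.center - p1.center
    dist = float(np.linalg.norm(d))
    if dist > 1e-12:
        delta = dist - ideal.pp_span
        mv = math.copysign(min(policy.step, abs(delta)), delta)
        n = d / dist
        move_node(p1, +0.5 * mv * n)
        move_node(p2, -0.5 * mv * n)

    # the basepair tube tracks its phosphates
    base.shape.end_a = p1.center.copy()
    base.shape.end_b = p2.center.copy()

    # helical twist refinement against the previous rung
    if prev_base is not None and len(prev_base.children) == 2:
        axis = grandparent.shape.axis
        v_prev = prev_base.children[1].center - prev_base.children[0].center
        v_cur = p2.center - p1.center
        v_prev = v_prev - np.dot(v_prev, axis) * axis
        v_cur = v_cur - np.dot(v_cur, axis) * axis
        if np.linalg.norm(v_prev) > 1e-9 and np.linalg.norm(v_cur) > 1e-9:
            v_prev = _unit(v_prev)
            v_cur = _unit(v_cur)
            cosang = float(np.clip(np.dot(v_prev, v_cur), -1.0, 1.0))
            sinang = float(np.dot(np.cross(v_prev, v_cur), axis))
            torsion = math.atan2(sinang, cosang)
            err = ideal.twist - torsion          # right-handed ideal > 0
            err = (err + math.pi) % (2 * math.pi) - math.pi
            max_step = policy.step / max(ideal.pp_span / 2.0, 1e-9)
            ang = math.copysign(min(abs(err), max_step), err)
            rot = _rotation_about(axis, ang)
            rotate_node(base, rot, base.shape.center)


def apply_keeper(root: Node, params: ParamSet) -> None:
    """One containment pass over the whole tree (parents in pre-order)."""
    for parent in iter_nodes(root):
        if not parent.children:
            continue
        rec = params.at(parent.level)
        keep = rec.keep
        if keep is None or keep == 0.0:
            continue
        s = parent.shape
        positive = keep > 0
        if isinstance(s, Sphere):
            mode = "inside" if positive else "on_surface"
            pol = KeepPolicy(abs(keep), mode, params.margin_in, params.margin_out)
            for ch in parent.children:
                pack_ball(parent, ch, pol)
        elif isinstance(s, Spheroid):
            mode = "inside" if positive else "on_surface"
            pol = KeepPolicy(abs(keep), mode, params.margin_in, params.margin_out)
            for ch in parent.children:
                pack_egg(parent, ch, pol)
        elif isinstance(s, Tube):
            mode = "on_surface" if positive else "inside"
            pol = KeepPolicy(abs(keep), mode, params.margin_in, params.margin_out)
            loop = parent.kind in ("sse_loop", "rna_loop")
            duplex = parent.kind in ("stemloop", "dna_segment")
            prev = None
            for ch in parent.children:
                if duplex and ch.kind == "basepair":
                    ideal = (constants.DNA_DUPLEX
                             if parent.kind == "dna_segment"
                             else constants.RNA_DUPLEX)
                    pack_base(parent, ch, pol, prev_base=prev, ideal=ideal)
                    prev = ch
                else:
                    pack_tube(parent, ch, pol, loop=loop)
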