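"""Hierarchical collision detection and count-dependent repulsion.

Collisions are resolved top-down: at each family (the children of one
node) violating pairs are found (:func:`get_bumps`), the worst first.  For
a colliding non-atomic pair the number of collisions between their children
is counted and corrected by :func:`bump_ex`, and the parents themselves are
then repelled by a step blended between the *soft* and *hard* parameters by
the child-collision count *m*:

    boot = f * soft + (1 - f) * hard,   f = exp(-m^2 / 100)

so a grazing container contact (m = 0) uses the soft step while a deeply
engaged one approaches the hard step ("currants in jelly").  Bonded or
linked pairs are exempt from mutual repulsion, but their children are still
examined.  All displacements are symmetric half-steps applied recursively
to whole subtrees, capped so a pair never overshoots the target gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hierarchy import Node, ParamRecord, ParamSet, move_node
from .shapes import Sphere, touch, _unit, TIE_BREAK

__all__ = ["BumpPair", "BumpLog", "get_bumps", "boot_step", "part2cells",
           "exempt", "bump_ex", "bump_in"]

#: Family size at and above which the axis-sweep candidate screen replaces
#: the exact all-pairs screen.
SWEEP_THRESHOLD = 20


@dataclass
class BumpPair:
    a: Node
    b: Node
    violation: float        # -gap, > 0 for listed pairs


@dataclass
class BumpLog:
    """Optional instrumentation: every leaf/node pair the pass acted on."""
    pairs: set = field(default_factory=set)
    count: int = 0

    def record(self, a: Node, b: Node) -> None:
        self.pairs.add((min(a.id, b.id), max(a.id, b.id)))
        self.count += 1


def exempt(a: Node, b: Node) -> bool:
    """True if the two objects are exempt from mutual collisions (bonded or
    joined by a live link)."""
    return a.exempt_with(b)


def boot_step(m: int, hard: float | None, soft: float | None) -> float:
    """Count-dependent repulsion step.

    The soft/hard blend applies only when both parameters are configured;
    otherwise the single configured value is used directly.
    """
    if hard is None and soft is None:
        return 0.0
    if hard is None:
        return soft
    if soft is None:
        return hard
    f = math.exp(-m * m / 100.0)
    return f * soft + (1.0 - f) * hard


def part2cells(a: Node, b: Node, step: float, target_gap: float = 0.0,
               contact=None) -> float:
    """Push two nodes symmetrically apart toward ``target_gap``.

    Each body (with its whole subtree) receives half the displacement along
    the contact normal, capped so the pair does not overshoot the target in
    one call.  Returns the displacement magnitude actually applied.
    """
    if step <= 0.0:
        return 0.0
    if contact is None:
        contact = touch(a.collision_shape(), b.collision_shape())
    deficit = target_gap - contact.gap
    if deficit <= 0.0:
        return 0.0
    mv = min(step, deficit)
    n = contact.normal
    move_node(a, -0.5 * mv * n)
    move_node(b, +0.5 * mv * n)
    return mv


def _pairwise_bumps(family: list[Node], target_gap: float) -> list[BumpPair]:
    out: list[BumpPair] = []
    n = len(family)
    # Fast path: families of spheres compare centre distances in one shot.
    if all(isinstance(x.shape, Sphere) for x in family):
        centers = np.array([x.center for x in family])
        radii = np.array([x.bump_radius for x in family])
        diff = centers[:, None, :] - centers[None, :, :]
        dist = np.sqrt((diff * diff).sum(axis=2))
        gaps = dist - (radii[:, None] + radii[None, :])
        ii, jj = np.where(gaps < target_gap)
        for i, j in zip(ii, jj):
            if i < j:
                out.append(BumpPair(family[i], family[j],
                                    float(target_gap - gaps[i, j])))
        return out
    for i in range(n):
        for j in range(i + 1, n):
            c = touch(family[i].collision_shape(), family[j].collision_shape())
            if c.gap < target_gap:
                out.append(BumpPair(family[i], family[j], target_gap - c.gap))
    return out


def _sweep_bumps(family: list[Node], target_gap: float) -> list[BumpPair]:
    """Axis-sweep candidate generation for large families.

    Each node projects to the interval centre +/- largest dimension on each
    world axis; only pairs whose intervals overlap on all three axes are
    checked exactly.  A conservative superset of the true overlap set.
    """
    n = len(family)
    centers = np.array([x.center for x in family])
    ext = np.array([x.max_extent() for x in family]) + max(0.0, target_gap)
    lo = centers - ext[:, None]
    hi = centers + ext[:, None]
    order = np.argsort(lo[:, 0], kind="stable")
    out: list[BumpPair] = []
    for oi in range(n):
        i = order[oi]
        for oj in range(oi + 1, n):
            j = order[oj]
            if lo[j, 0] > hi[i, 0]:
                break
            if lo[j, 1] > hi[i, 1] or lo[i, 1] > hi[j, 1]:
                continue
            if lo[j, 2] > hi[i, 2] or lo[i, 2] > hi[j, 2]:
                continue
            c = touch(family[i].collision_shape(), family[j].collision_shape())
            if c.gap < target_gap:
                out.append(BumpPair(family[i], family[j], target_gap - c.gap))
    return out


def get_bumps(family: list[Node], target_gap: float = 0.0) -> list[BumpPair]:
    """Violating sibling pairs, sorted by descending degree of violation.

    Small families (< 20) use the exact all-pairs screen; larger ones the
    axis-sweep candidate screen followed by exact checks.
    """
    if len(family) < 2:
        return []
    if len(family) < SWEEP_THRESHOLD:
        out = _pairwise_bumps(family, target_gap)
    else:
        out = _sweep_bumps(family, target_gap)
    out.sort(key=lambda bp: -bp.violation)
    return out


def _nudge_home(child: Node, magnitude: float) -> None:
    if magnitude <= 0.0 or child.parent is None:
        return
    d = child.parent.center - child.center
    n = _unit(d, fallback=TIE_BREAK)
    move_node(child, magnitude * n)


def bump_ex(a: Node, b: Node, params: ParamSet, log: BumpLog | None = None) -> int:
    """Count and correct collisions between the children of two colliding
    parents; returns the number of colliding child pairs.

    Each clashing cross-family pair is nudged back toward its own parent
    centre (always soft/10) and then separated -- by the hard step if the
    children are atoms, by the soft step otherwise.  The routine recurses
    into the children of clashing child pairs; recursive corrections do not
    add to the returned count.
    """
    ca = a.children if a.children else [a]
    cb = b.children if b.children else [b]
    if ca[0] is a and cb[0] is b:
        # Childless inputs: the (a, b) clash itself is the count.
        return 1 if touch(a.collision_shape(), b.collision_shape()).gap < 0 else 0
    child_level = max(a.level, b.level) + 1
    rec = params.at(child_level)
    soft = rec.soft if rec.soft is not None else (rec.hard or 0.0)
    m = 0
    # Vectorised sphere screen over the cross product of the two families.
    if all(isinstance(x.shape, Sphere) for x in ca) and \
            all(isinstance(x.shape, Sphere) for x in cb):
        pa = np.array([x.center for x in ca])
        pb = np.array([x.center for x in cb])
        ra = np.array([x.bump_radius for x in ca])
        rb = np.array([x.bump_radius for x in cb])
        diff = pa[:, None, :] - pb[None, :, :]
        gaps = np.sqrt((diff * diff).sum(axis=2)) - (ra[:, None] + rb[None, :])
        clashing = list(zip(*np.where(gaps < 0.0)))
    else:
        clashing = []
        for i, x in enumerate(ca):
            for j, y in enumerate(cb):
                if touch(x.collision_shape(), y.collision_shape()).gap < 0.0:
                    clashing.append((i, j))
    for i, j in clashing:
        x, y = ca[i], cb[j]
        if not exempt(x, y):
            m += 1
            if log is not None:
                log.record(x, y)
            atoms = x.is_leaf and y.is_leaf
            kick = (rec.hard if rec.hard is not None else soft) if atoms else soft
            _nudge_home(x, soft / 10.0)
            _nudge_home(y, soft / 10.0)
            part2cells(x, y, kick)
        # Children of exempt pairs might still be in collision.
        if x.children and y.children:
            bump_ex(x, y, params, log)
    return m


def bump_in(node: Node, params: ParamSet, log: BumpLog | None = None) -> None:
    """One depth-first hierarchical collision pass over a subtree.

    At each family the violating pairs are processed worst-first: non-atomic
    pairs have their children counted and corrected by :func:`bump_ex`, and
    unless exempt the pair itself is repelled by the blended boot step (the
    plain hard step for atoms, where only hard applies).
    """
    fam = node.children
    if len(fam) >= 2:
        child_level = node.level + 1
        rec = params.at(child_level)
        for bp in get_bumps(fam):
            a, b = bp.a, bp.b
            if a.is_leaf and b.is_leaf:
                if not exempt(a, b):
                    if log is not None:
                        log.record(a, b)
                    part2cells(a, b, rec.hard if rec.hard is not None
                               else (rec.soft or 0.0))
            else:
                m = bump_ex(a, b, params, log)
                if not exempt(a, b):
                    if log is not None:
                        log.record(a, b)
                    part2cells(a, b, boot_step(m, rec.hard, rec.soft))
    for c in node.children:
        bump_in(c, params, log)
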