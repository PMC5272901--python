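"""The nested object tree: levels, parent-child coupling, rigid motions.

A :class:`Node` owns a shape (its container geometry), an ordered list of
children, and bookkeeping for bonds and breakable links.  Levels count from
0 at the root downward to the atoms, which are always hard spheres.  Two
couplings tie the levels together: any rigid motion of a parent is applied
recursively to its whole subtree, and parent centres track the centroid of
their children (:func:`sync_centers`).  Orientation of elongated containers
is re-derived from the children either from the chain termini or from the
moments of inertia of the point set (:func:`realign_axis`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .shapes import Shape, Sphere, Spheroid, Tube, _any_perpendicular, _unit

__all__ = [
    "Node", "Bond", "Link", "ParamRecord", "ParamSet",
    "move_node", "rotate_node", "sync_centers", "realign_axis",
    "fit_container", "iter_nodes", "leaves",
]

_node_counter = itertools.count()


@dataclass
class Bond:
    partner: "Node"
    target: float
    kind: str = "chain"          # chain | stack | segment


@dataclass
class Link:
    partner: "Node"
    target: float
    strength: float = 1.0
    live: bool = True
    max_extension: float = 1.5   # break beyond target * max_extension


class Node:
    """One object in the hierarchy tree."""

    def __init__(self, shape: Shape, level: int = 0, kind: str = "generic",
                 bump_radius: float | None = None, label: str | None = None):
        self.id = next(_node_counter)
        self.shape = shape
        self.level = level
        self.kind = kind
        self.label = label
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.bonds: list[Bond] = []
        self.links: list[Link] = []
        self._exempt_ids: set[int] = set()
        if bump_radius is None:
            if isinstance(shape, Sphere) or isinstance(shape, Tube):
                bump_radius = shape.radius
            else:
                bump_radius = shape.semi_transverse
        self.bump_radius = float(bump_radius)

    # -- structure ---------------------------------------------------------

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def center(self) -> np.ndarray:
        return self.shape.center

    def collision_shape(self) -> Shape:
        """The shape used for bumping: the container geometry with its
        radial dimension replaced by the node's bump radius."""
        s = self.shape
        if isinstance(s, Sphere):
            if self.bump_radius == s.radius:
                return s
            return Sphere(s.center, self.bump_radius)
        if isinstance(s, Tube):
            if self.bump_radius == s.radius:
                return s
            return Tube(s.end_a, s.end_b, self.bump_radius)
        scale = self.bump_radius / s.semi_transverse
        if scale == 1.0:
            return s
        return Spheroid(s.center, s.axis, s.semi_axial * scale,
                        self.bump_radius)

    def max_extent(self) -> float:
        """Largest dimension of the collision shape: the maximum axis length
        of a spheroid or the larger of length and diameter of a tube.  Used
        by the axis-sweep candidate screen."""
        s = self.shape
        if isinstance(s, Sphere):
            return self.bump_radius
        if isinstance(s, Tube):
            return 0.5 * s.length + self.bump_radius
        scale = self.bump_radius / s.semi_transverse
        return max(s.semi_axial * scale, self.bump_radius)

    # -- bonds & links -----------------------------------------------------

    def bond_to(self, other: "Node", target: float, kind: str = "chain") -> None:
        self.bonds.append(Bond(other, float(target), kind))
        self._exempt_ids.add(other.id)
        other._exempt_ids.add(self.id)

    def link_to(self, other: "Node", target: float, strength: float = 1.0,
                max_extension: float = 1.5) -> Link:
        lk = Link(other, float(target), float(strength), True, max_extension)
        self.links.append(lk)
        self._exempt_ids.add(other.id)
        other._exempt_ids.add(self.id)
        return lk

    def break_link(self, lk: Link) -> None:
        lk.live = False
        self._rebuild_exemptions()
        lk.partner._rebuild_exemptions()

    def _rebuild_exemptions(self) -> None:
        ids = {b.partner.id for b in self.bonds}
        ids |= {l.partner.id for l in self.links if l.live}
        self._exempt_ids = ids

    def exempt_with(self, other: "Node") -> bool:
        """True iff the two nodes are bonded or joined by a live link."""
        return other.id in self._exempt_ids or self.id in other._exempt_ids

    def __repr__(self):  # pragma: no cover
        return (f"Node(id={self.id}, level={self.level}, kind={self.kind}, "
                f"shape={type(self.shape).__name__}, "
                f"children={len(self.children)})")


@dataclass
class ParamRecord:
    """Per-level step sizes.  ``None`` means the parameter is unset; when
    only one of hard/soft is configured that value is used directly without
    the count-dependent blend."""
    hard: float | None = None
    soft: float | None = None
    keep: float | None = None
    bump: float = 1.0
    bond: float | None = None


@dataclass
class ParamSet:
    """Per-level parameter records plus global settings."""
    levels: dict[int, ParamRecord] = field(default_factory=dict)
    slow_factor: float = 1.0
    margin_in: float = 0.9
    margin_out: float = 1.1

    def at(self, level: int) -> ParamRecord:
        return self.levels.get(level, ParamRecord())

    def scaled(self, factor: float) -> "ParamSet":
        """All kick magnitudes multiplied by ``factor`` (slow-motion)."""
        recs = {}
        for lv, r in self.levels.items():
            recs[lv] = ParamRecord(
                None if r.hard is None else r.hard * factor,
                None if r.soft is None else r.soft * factor,
                None if r.keep is None else r.keep * factor,
                r.bump,
                None if r.bond is None else r.bond * factor)
        return ParamSet(recs, self.slow_factor, self.margin_in, self.margin_out)


# ---------------------------------------------------------------------------
# traversal helpers

def iter_nodes(root: Node):
    """Depth-first pre-order iteration over a subtree."""
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.children))


def leaves(root: Node) -> list[Node]:
    return [n for n in iter_nodes(root) if n.is_leaf]


# ---------------------------------------------------------------------------
# rigid motions

def move_node(n: Node, d: np.ndarray) -> None:
    """Translate a node and, recursively, its whole subtree."""
    d = np.asarray(d, dtype=float)
    for sub in iter_nodes(n):
        sub.shape.translate(d)


def rotate_node(n: Node, rot: np.ndarray, about: np.ndarray) -> None:
    """Rotate a subtree rigidly about a point.

    ``rot`` must be a proper rotation matrix (orthonormal, det +1).
    """
    rot = np.asarray(rot, dtype=float)
    if rot.shape != (3, 3) or not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9) \
            or abs(np.linalg.det(rot) - 1.0) > 1e-9:
        raise ValueError("rotation must be orthonormal with det +1")
    about = np.asarray(about, dtype=float)
    for sub in iter_nodes(n):
        sub.shape.transform(rot, about)


# ---------------------------------------------------------------------------
# centroid tracking and axis realignment

def sync_centers(root: Node) -> None:
    """Re-centre every non-leaf container at the centroid of its children.

    Processed leaf-to-root so parents see updated child positions.  Tubes
    are re-centred by their axis midpoint, preserving direction and length.
    Childless non-leaf nodes cannot occur; childless roots are left alone.
    """
    order: list[Node] = list(iter_nodes(root))
    for n in reversed(order):
        if n.children:
            centroid = np.mean([c.center for c in n.children], axis=0)
            n.shape.set_center(centroid)


def realign_axis(n: Node, method: str = "termini", k: int = 3) -> None:
    """Re-derive the symmetry axis of a tube or spheroid container from its
    leaf descendants.

    ``termini``: unit vector from the mean of the first ``k`` leaf positions
    to the mean of the last ``k`` (duplex nucleic-acid containers group the
    complementary 5'/3' pairs jointly, which the basepair leaf ordering
    already provides).  ``inertia``: principal eigenvector of the
    leaf-position inertia tensor.  The new axis keeps the sign closest to
    the old one; isotropic point sets leave the axis unchanged.  Shape
    dimensions are never altered.
    """
    if isinstance(n.shape, Sphere):
        return
    lv = leaves(n)
    if len(lv) < 2:
        return
    pts = np.array([x.center for x in lv])
    old_axis = n.shape.axis
    if method == "termini":
        k = min(k, len(lv) // 2) or 1
        head = pts[:k].mean(axis=0)
        tail = pts[-k:].mean(axis=0)
        d = tail - head
        if np.linalg.norm(d) < 1e-12:
            return
        axis = _unit(d)
    elif method == "inertia":
        centred = pts - pts.mean(axis=0)
        cov = centred.T @ centred
        w, v = np.linalg.eigh(cov)
        if w[-1] < 1e-24 or (w[-1] - w[-2]) <= 1e-9 * max(w[-1], 1e-300):
            return  # isotropic / degenerate: leave axis unchanged
        axis = v[:, -1]
    else:
        raise ValueError(f"unknown realignment method: {method!r}")
    if float(np.dot(axis, old_axis)) < 0:
        axis = -axis
    _set_axis(n.shape, axis)


def _set_axis(shape: Shape, axis: np.ndarray) -> None:
    if isinstance(shape, Tube):
        c = shape.center
        half = 0.5 * shape.length
        shape.end_a = c - half * axis
        shape.end_b = c + half * axis
    elif isinstance(shape, Spheroid):
        shape.axis = axis


# ---------------------------------------------------------------------------
# container fitting

def fit_container(points, kind: str, padding: float = 0.0) -> Shape:
    """Fit an enclosing container of the requested kind to a point set.

    sphere: centroid centre, max-distance radius.  tube: inertia axis,
    length spanning the axial extent, radius spanning the transverse extent.
    spheroid: the closest symmetric (prolate or oblate) fit to the inertia
    eigen-extents, inflated so every point lies inside.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("fit_container needs at least 2 points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    if kind == "sphere":
        r = float(np.linalg.norm(centred, axis=1).max()) + padding
        return Sphere(centroid, max(r, max(padding, 1e-6)))

    cov = centred.T @ centred
    w, v = np.linalg.eigh(cov)       # ascending eigenvalues
    axes = v.T[::-1]                 # descending principal directions
    proj = centred @ axes.T          # coordinates in principal frame
    ext = np.abs(proj).max(axis=0)   # max |coordinate| per principal axis

    if kind == "tube":
        axis = axes[0]
        if float(ext[0]) < 1e-12:
            axis = _any_perpendicular(np.array([0.0, 0.0, 1.0]))
        half = float(ext[0])
        r = float(np.hypot(proj[:, 1], proj[:, 2]).max()) + padding
        r = max(r, max(padding, 1e-6))
        return Tube(centroid - half * axis, centroid + half * axis, r)

    if kind == "spheroid":
        e1, e2, e3 = float(ext[0]), float(ext[1]), float(ext[2])
        floor = max(padding, 1e-6)
        if (e1 - e2) > (e2 - e3):
            # unique long axis: prolate
            axis = axes[0]
            a = max(e1 + padding, floor)
            b = max(0.5 * (e2 + e3) + padding, floor)
        else:
            # unique short axis: oblate
            axis = axes[2]
            a = max(e3 + padding, floor)
            b = max(0.5 * (e1 + e2) + padding, floor)
        egg = Spheroid(centroid, axis, a, b)
        # inflate uniformly until all points are inside
        g = np.sqrt(np.maximum(0.0, np.array([egg.implicit(p) for p in pts]) + 1.0))
        scale = float(g.max())
        if scale > 1.0:
            egg = Spheroid(centroid, axis, a * scale, b * scale)
        return egg

    raise ValueError(f"unknown container kind: {kind!r}")
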