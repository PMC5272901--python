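"""Shape primitives and pairwise surface-gap / contact-normal computations.

Three convex primitives are supported: the sphere, the tube (a straight
cylinder with hemispherical end-caps, i.e. a capsule) and the spheroid (an
ellipsoid of rotation, prolate or oblate but never scalene).  For every pair
of primitives :func:`touch` returns a :class:`Contact` carrying the signed
surface-surface gap (negative on inter-penetration), the closest surface
points and the contact normal along which repulsion kicks act.

Sphere and tube encounters reduce to point/segment and segment/segment
distances.  Spheroid encounters exploit the ellipse-of-rotation: every
query point is reduced to the meridional half-plane (radial, axial), where
the focal-sum construction gives a cheap inside/outside estimate
(:func:`in_egg`) and a bracketed 1-D root find gives the exact signed
distance and nearest surface point (:func:`vec_to_egg`).  The
spheroid-spheroid contact normal, which has no closed form, is found by a
recursive quad-section of octant triangulations of both surfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "Sphere",
    "Tube",
    "Spheroid",
    "Contact",
    "touch",
    "gap_sphere_sphere",
    "gap_sphere_tube",
    "gap_tube_tube",
    "gap_sphere_spheroid",
    "gap_tube_spheroid",
    "contact_spheroid_spheroid",
    "spheroid_contact_search",
    "focal_half_distance",
    "in_egg",
    "vec_to_egg",
    "radial_project",
]

#: Deterministic tie-break direction for degenerate geometry (coincident
#: centers, point exactly on an axis): +x of the local/world frame.
TIE_BREAK = np.array([1.0, 0.0, 0.0])

#: Focal-excess scale of the cheap spheroid distance estimate.  The raw
#: focal-sum excess is twice the true distance in the sphere limit; halving
#: it and applying the empirical 1.4 factor gives 0.7.  Only sign and
#: ordering of in_egg values are ever used for decisions, so this constant
#: affects screening efficiency, not results.
IN_EGG_SCALE = 0.7

#: Tube-axis bisection terminates when the bracket is narrower than this.
AXIS_BISECT_TOL = 1e-4

#: Depth of the recursive quad-section in the spheroid-spheroid search.
QUAD_SECTION_DEPTH = 3


def _as_vec(v) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError("coordinates must be finite")
    return a


def _unit(v: np.ndarray, fallback: np.ndarray | None = None) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-300:
        if fallback is None:
            fallback = TIE_BREAK
        return np.array(fallback, dtype=float)
    return v / n


def _any_perpendicular(axis: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to ``axis`` (prefers +x)."""
    p = TIE_BREAK - np.dot(TIE_BREAK, axis) * axis
    n = float(np.linalg.norm(p))
    if n < 1e-8:
        p = np.array([0.0, 1.0, 0.0]) - axis[1] * axis
        n = float(np.linalg.norm(p))
    return p / n


@dataclass
class Sphere:
    center: np.ndarray
    radius: float

    def __post_init__(self):
        self.center = _as_vec(self.center)
        if self.radius <= 0:
            raise ValueError("sphere radius must be > 0")

    def translate(self, d: np.ndarray) -> None:
        self.center = self.center + d

    def transform(self, rot: np.ndarray, about: np.ndarray) -> None:
        self.center = about + rot @ (self.center - about)

    def set_center(self, c: np.ndarray) -> None:
        self.center = _as_vec(c)

    def copy(self) -> "Sphere":
        return Sphere(self.center.copy(), self.radius)


@dataclass
class Tube:
    """Fixed-length straight pipe with hemispherical end-caps (capsule)."""

    end_a: np.ndarray
    end_b: np.ndarray
    radius: float

    def __post_init__(self):
        self.end_a = _as_vec(self.end_a)
        self.end_b = _as_vec(self.end_b)
        if self.radius <= 0:
            raise ValueError("tube radius must be > 0")

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.end_a + self.end_b)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end_b - self.end_a))

    @property
    def axis(self) -> np.ndarray:
        return _unit(self.end_b - self.end_a)

    def translate(self, d: np.ndarray) -> None:
        self.end_a = self.end_a + d
        self.end_b = self.end_b + d

    def transform(self, rot: np.ndarray, about: np.ndarray) -> None:
        self.end_a = about + rot @ (self.end_a - about)
        self.end_b = about + rot @ (self.end_b - about)

    def set_center(self, c: np.ndarray) -> None:
        d = _as_vec(c) - self.center
        self.translate(d)

    def copy(self) -> "Tube":
        return Tube(self.end_a.copy(), self.end_b.copy(), self.radius)


@dataclass
class Spheroid:
    """Ellipsoid of rotation: two equal transverse semi-axes, one axial.

    Prolate when ``semi_axial > semi_transverse`` (cigar), oblate when
    smaller (flying saucer), a sphere when equal.  Scalene ellipsoids are
    deliberately unsupported.
    """

    center: np.ndarray
    axis: np.ndarray
    semi_axial: float
    semi_transverse: float

    def __post_init__(self):
        self.center = _as_vec(self.center)
        self.axis = _unit(_as_vec(self.axis))
        if self.semi_axial <= 0 or self.semi_transverse <= 0:
            raise ValueError("spheroid semi-axes must be > 0")

    def translate(self, d: np.ndarray) -> None:
        self.center = self.center + d

    def transform(self, rot: np.ndarray, about: np.ndarray) -> None:
        self.center = about + rot @ (self.center - about)
        self.axis = _unit(rot @ self.axis)

    def set_center(self, c: np.ndarray) -> None:
        self.center = _as_vec(c)

    def copy(self) -> "Spheroid":
        return Spheroid(self.center.copy(), self.axis.copy(),
                        self.semi_axial, self.semi_transverse)

    def meridional(self, p: np.ndarray) -> tuple[float, float, np.ndarray]:
        """Reduce point ``p`` to (radial u >= 0, axial v, radial unit dir)."""
        q = np.asarray(p, dtype=float) - self.center
        v = float(np.dot(q, self.axis))
        rad = q - v * self.axis
        u = float(np.linalg.norm(rad))
        if u < 1e-12:
            rdir = _any_perpendicular(self.axis)
        else:
            rdir = rad / u
        return u, v, rdir

    def implicit(self, p: np.ndarray) -> float:
        """(u/b)^2 + (v/a)^2 - 1; negative strictly inside."""
        u, v, _ = self.meridional(p)
        return (u / self.semi_transverse) ** 2 + (v / self.semi_axial) ** 2 - 1.0


Shape = Sphere | Tube | Spheroid


@dataclass
class Contact:
    """Signed surface gap plus contact geometry for a shape pair.

    ``gap`` is negative on inter-penetration.  ``normal`` points from shape
    *a* toward shape *b* in the sense that displacing *b* along ``+normal``
    (and *a* along ``-normal``) increases the gap.
    """

    gap: float
    point_a: np.ndarray
    point_b: np.ndarray
    normal: np.ndarray

    def flipped(self) -> "Contact":
        return Contact(self.gap, self.point_b.copy(), self.point_a.copy(),
                       -self.normal)


# ---------------------------------------------------------------------------
# segment helpers

def _closest_on_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(np.dot(ab, ab))
    if denom < 1e-300:
        return a.copy()
    t = float(np.dot(p - a, ab)) / denom
    t = min(1.0, max(0.0, t))
    return a + t * ab


def _closest_between_segments(p1, q1, p2, q2):
    """Closest points between segments [p1,q1] and [p2,q2].

    Standard clamped quadratic minimisation; parallel overlapping axes are
    tie-broken at the midpoint of the overlap.
    """
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(np.dot(d1, d1))
    e = float(np.dot(d2, d2))
    f = float(np.dot(d2, r))
    EPS = 1e-14
    if a <= EPS and e <= EPS:
        return p1.copy(), p2.copy()
    if a <= EPS:
        s = 0.0
        t = min(1.0, max(0.0, f / e))
    else:
        c = float(np.dot(d1, r))
        if e <= EPS:
            t = 0.0
            s = min(1.0, max(0.0, -c / a))
        else:
            b = float(np.dot(d1, d2))
            denom = a * e - b * b
            if denom > EPS * a * e:
                s = min(1.0, max(0.0, (b * f - c * e) / denom))
            else:
                # Parallel axes: centre of the parameter overlap on segment 1.
                s0 = min(1.0, max(0.0, -c / a))
                s1 = min(1.0, max(0.0, (b - c) / a))
                s = 0.5 * (s0 + s1)
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(1.0, max(0.0, -c / a))
            elif t > 1.0:
                t = 1.0
                s = min(1.0, max(0.0, (b - c) / a))
    return p1 + s * d1, p2 + t * d2


# ---------------------------------------------------------------------------
# sphere / tube encounters

def gap_sphere_sphere(a: Sphere, b: Sphere) -> Contact:
    d = b.center - a.center
    dist = float(np.linalg.norm(d))
    n = _unit(d) if dist > 1e-12 else TIE_BREAK.copy()
    gap = dist - (a.radius + b.radius)
    return Contact(gap, a.center + a.radius * n, b.center - b.radius * n, n)


def gap_sphere_tube(s: Sphere, t: Tube) -> Contact:
    cp = _closest_on_segment(s.center, t.end_a, t.end_b)
    d = cp - s.center
    dist = float(np.linalg.norm(d))
    if dist > 1e-12:
        n = d / dist
    else:
        # Sphere centre on the axis: radial tie-break.
        n = _any_perpendicular(t.axis) if t.length > 1e-12 else TIE_BREAK.copy()
    gap = dist - (s.radius + t.radius)
    return Contact(gap, s.center + s.radius * n, cp - t.radius * n, n)


def gap_tube_tube(t1: Tube, t2: Tube) -> Contact:
    c1, c2 = _closest_between_segments(t1.end_a, t1.end_b, t2.end_a, t2.end_b)
    d = c2 - c1
    dist = float(np.linalg.norm(d))
    n = _unit(d) if dist > 1e-12 else _any_perpendicular(t1.axis)
    gap = dist - (t1.radius + t2.radius)
    return Contact(gap, c1 + t1.radius * n, c2 - t2.radius * n, n)


# ---------------------------------------------------------------------------
# spheroid utilities

def focal_half_distance(e: Spheroid) -> float:
    """c = sqrt(major^2 - minor^2) of the meridional ellipse (0 for a sphere)."""
    major = max(e.semi_axial, e.semi_transverse)
    minor = min(e.semi_axial, e.semi_transverse)
    return math.sqrt(max(0.0, major * major - minor * minor))


def _foci_2d(e: Spheroid) -> tuple[tuple[float, float], tuple[float, float], float]:
    """2-D foci in (u, v) meridional coordinates plus the major semi-axis.

    For oblate spheroids the 3-D foci form a ring; working in the meridional
    half-plane reduces both cases to a single ellipse.
    """
    c = focal_half_distance(e)
    if e.semi_axial >= e.semi_transverse:      # prolate or sphere: foci on axis
        return (0.0, c), (0.0, -c), e.semi_axial
    return (c, 0.0), (-c, 0.0), e.semi_transverse


def in_egg(p: np.ndarray, e: Spheroid) -> float:
    """Approximate signed distance from ``p`` to the spheroid surface.

    Scaled focal-sum excess: zero on the surface, negative inside.  The
    magnitude is only an estimate; use :func:`vec_to_egg` for true values.
    """
    u, v, _ = e.meridional(p)
    (f1u, f1v), (f2u, f2v), major = _foci_2d(e)
    d1 = math.hypot(u - f1u, v - f1v)
    d2 = math.hypot(u - f2u, v - f2v)
    return IN_EGG_SCALE * (d1 + d2 - 2.0 * major)


def _point_to_ellipse(e0: float, e1: float, y0: float, y1: float):
    """Closest point on the ellipse (x0/e0)^2 + (x1/e1)^2 = 1 to (y0, y1).

    Requires e0 >= e1 > 0 and y0, y1 >= 0.  Returns (x0, x1, dist) with the
    unsigned distance.  Robust bracketed root find on the standard rational
    function of the Lagrange parameter.
    """
    if y1 > 0.0:
        if y0 > 0.0:
            z0 = y0 / e0
            z1 = y1 / e1
            g = z0 * z0 + z1 * z1 - 1.0
            if abs(g) < 1e-14:
                return y0, y1, 0.0
            e0sq = e0 * e0
            e1sq = e1 * e1
            n0 = e0 * y0
            n1 = e1 * y1
            # F(t) = (n0/(t+e0^2))^2 + (n1/(t+e1^2))^2 - 1 is convex and
            # strictly decreasing on (-e1^2, inf), so Newton started at the
            # analytic left bracket converges monotonically to the root.
            t = -e1sq + n1
            for _ in range(100):
                a0 = n0 / (t + e0sq)
                a1 = n1 / (t + e1sq)
                f = a0 * a0 + a1 * a1 - 1.0
                if f < 1e-14:
                    break
                df = -2.0 * (a0 * a0 / (t + e0sq) + a1 * a1 / (t + e1sq))
                t -= f / df
            x0 = e0sq * y0 / (t + e0sq)
            x1 = e1sq * y1 / (t + e1sq)
            return x0, x1, math.hypot(x0 - y0, x1 - y1)
        # On the minor axis: the nearer minor vertex is closest (e0 >= e1).
        return 0.0, e1, abs(y1 - e1)
    # y1 == 0: on the major axis; closest point may be off-axis inside the
    # evolute of the ellipse.
    denom = e0 * e0 - e1 * e1
    numer = e0 * y0
    if denom > 0.0 and numer < denom:
        xbar = numer / denom
        x0 = e0 * xbar
        x1 = e1 * math.sqrt(max(0.0, 1.0 - xbar * xbar))
        return x0, x1, math.hypot(x0 - y0, x1)
    return e0, 0.0, abs(y0 - e0)


def vec_to_egg(p: np.ndarray, e: Spheroid) -> tuple[float, np.ndarray]:
    """Exact signed distance from ``p`` to the spheroid surface and the foot.

    Negative inside.  The 3-D problem is reduced to point-to-ellipse in the
    meridional half-plane.
    """
    u, v, rdir = e.meridional(p)
    b = e.semi_transverse
    a = e.semi_axial
    sv = 1.0 if v >= 0 else -1.0
    av = abs(v)
    # clamp vanishing coordinates onto the axes for numerical stability
    if av < 1e-12 * a:
        av = 0.0
    if u < 1e-12 * b:
        u = 0.0
    if b >= a:
        x0, x1, dist = _point_to_ellipse(b, a, u, av)
        fu, fv = x0, x1
    else:
        x0, x1, dist = _point_to_ellipse(a, b, av, u)
        fu, fv = x1, x0
    inside = (u / b) ** 2 + (v / a) ** 2 < 1.0
    foot = e.center + fu * rdir + sv * fv * e.axis
    return (-dist if inside else dist), foot


def radial_project(p: np.ndarray, e: Spheroid) -> np.ndarray:
    """Intersection of the ray centre->p with the spheroid surface."""
    q = np.asarray(p, dtype=float) - e.center
    v = float(np.dot(q, e.axis))
    usq = float(np.dot(q, q)) - v * v
    s = v * v / (e.semi_axial ** 2) + max(0.0, usq) / (e.semi_transverse ** 2)
    if s < 1e-300:
        raise ValueError("radial_project undefined at the spheroid centre")
    return e.center + q / math.sqrt(s)


# ---------------------------------------------------------------------------
# spheroid encounters

def gap_sphere_spheroid(s: Sphere, e: Spheroid) -> Contact:
    dist, foot = vec_to_egg(s.center, e)
    n = _unit(foot - s.center, fallback=_any_perpendicular(e.axis))
    if dist < 0.0:
        n = -n
    gap = dist - s.radius
    return Contact(gap, s.center + s.radius * n, foot, n)


def _axis_bisect_in_egg(t: Tube, e: Spheroid) -> float:
    """Parameter in [0,1] on the tube axis minimising the in_egg estimate.

    Three-point bracket; the worst end is discarded and the surviving
    interval re-bisected until narrower than AXIS_BISECT_TOL (absolute, in
    axis-parameter times length units).
    """
    pa, pb = t.end_a, t.end_b
    length = t.length
    if length < 1e-12:
        return 0.5

    def f(s):
        return in_egg(pa + s * (pb - pa), e)

    s1, s2, s3 = 0.0, 0.5, 1.0
    f1, f2, f3 = f(s1), f(s2), f(s3)
    tol = AXIS_BISECT_TOL / length
    while (s3 - s1) > tol:
        if f1 >= f3:
            # Discard the left end; re-bisect the surviving pair (s2, s3).
            s1, f1 = s2, f2
        else:
            # Discard the right end; re-bisect (s1, s2).
            s3, f3 = s2, f2
        s2 = 0.5 * (s1 + s3)
        f2 = f(s2)
    return min((f1, s1), (f2, s2), (f3, s3))[1]


def gap_tube_spheroid(t: Tube, e: Spheroid) -> Contact:
    if t.length < 1e-12:
        c = gap_sphere_spheroid(Sphere(t.center, t.radius), e)
        return c
    s_best = _axis_bisect_in_egg(t, e)
    pa, pb = t.end_a, t.end_b

    # Polish against the exact distance in a local window; the estimate and
    # the true distance share a minimiser only approximately.
    from scipy.optimize import minimize_scalar
    w = max(AXIS_BISECT_TOL / t.length, 0.05)
    lo, hi = max(0.0, s_best - w), min(1.0, s_best + w)
    res = minimize_scalar(lambda s: vec_to_egg(pa + s * (pb - pa), e)[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    # Guard against a minimiser hidden outside the window (flat estimates).
    res2 = minimize_scalar(lambda s: vec_to_egg(pa + s * (pb - pa), e)[0],
                           bounds=(0.0, 1.0), method="bounded",
                           options={"xatol": 1e-12})
    s_fin = res.x if res.fun <= res2.fun else res2.x
    axis_pt = pa + s_fin * (pb - pa)
    dist, foot = vec_to_egg(axis_pt, e)
    n = _unit(foot - axis_pt, fallback=_any_perpendicular(t.axis))
    if dist < 0.0:
        n = -n
    gap = dist - t.radius
    return Contact(gap, axis_pt + t.radius * n, foot, n)


# -- spheroid / spheroid ----------------------------------------------------

def _octant_frame(e: Spheroid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u3 = e.axis
    u1 = _any_perpendicular(u3)
    u2 = np.cross(u3, u1)
    return u1, u2, u3


def _octant_triangles(e: Spheroid) -> list[np.ndarray]:
    """The 8 octant triangles spanned by the 6 axis end-points."""
    u1, u2, u3 = _octant_frame(e)
    b, a = e.semi_transverse, e.semi_axial
    tris = []
    for s3 in (1.0, -1.0):
        pole = e.center + s3 * a * u3
        for s1 in (1.0, -1.0):
            v1 = e.center + s1 * b * u1
            for s2 in (1.0, -1.0):
                v2 = e.center + s2 * b * u2
                tris.append(np.array([pole, v1, v2]))
    return tris


def _tri_mid(tri: np.ndarray, e: Spheroid) -> np.ndarray:
    return radial_project(tri.mean(axis=0), e)


def _quad_sect(tri: np.ndarray, e: Spheroid) -> list[np.ndarray]:
    """Four sub-triangles from projected edge mid-points (no elongation)."""
    a, b, c = tri
    mab = radial_project(0.5 * (a + b), e)
    mbc = radial_project(0.5 * (b + c), e)
    mca = radial_project(0.5 * (c + a), e)
    return [np.array([a, mab, mca]), np.array([b, mbc, mab]),
            np.array([c, mca, mbc]), np.array([mab, mbc, mca])]


def _nine_points(mid: np.ndarray, tri: np.ndarray, e: Spheroid) -> list[np.ndarray]:
    """3x3 grid of surface points around a winning mid-point."""
    h1 = 0.5 * (tri[0] - mid)
    h2 = 0.5 * (tri[1] - mid)
    pts = []
    for i in (-1.0, 0.0, 1.0):
        for j in (-1.0, 0.0, 1.0):
            q = mid + i * h1 + j * h2
            if np.allclose(q, e.center):
                q = mid
            pts.append(radial_project(q, e))
    return pts


def spheroid_contact_search(e1: Spheroid, e2: Spheroid,
                            depth: int = QUAD_SECTION_DEPTH):
    """Recursive quad-section contact search between two spheroid surfaces.

    Octant triangulation of each surface (8 triangles from the 6 axis
    end-points), ranking of all 64 triangle-pair mid-point distances, descent
    of the top three pairs by quad-section to ``depth``, then a 9-point grid
    refinement around each winning mid-point.

    Returns ``(x1, x2, discrepancy)`` where ``x1, x2`` are the candidate
    contact points and ``discrepancy`` is the relative disagreement of the
    two exact point-to-surface validation distances (each candidate point
    against the opposing spheroid) -- the self-consistency figure of merit of
    the search itself.
    """
    tris1 = _octant_triangles(e1)
    tris2 = _octant_triangles(e2)
    mids1 = [_tri_mid(t, e1) for t in tris1]
    mids2 = [_tri_mid(t, e2) for t in tris2]
    ranked = sorted(
        ((np.linalg.norm(m1 - m2), i, j)
         for i, m1 in enumerate(mids1) for j, m2 in enumerate(mids2)),
        key=lambda r: r[0])

    best = None
    for _, i0, j0 in ranked[:3]:
        t1, t2 = tris1[i0], tris2[j0]
        for _ in range(depth):
            subs1 = _quad_sect(t1, e1)
            subs2 = _quad_sect(t2, e2)
            m1s = [_tri_mid(s, e1) for s in subs1]
            m2s = [_tri_mid(s, e2) for s in subs2]
            bi, bj, bd = 0, 0, np.inf
            for ii, m1 in enumerate(m1s):
                for jj, m2 in enumerate(m2s):
                    d = float(np.linalg.norm(m1 - m2))
                    if d < bd:
                        bi, bj, bd = ii, jj, d
            t1, t2 = subs1[bi], subs2[bj]
        m1 = _tri_mid(t1, e1)
        m2 = _tri_mid(t2, e2)
        p1s = _nine_points(m1, t1, e1)
        p2s = _nine_points(m2, t2, e2)
        for q1 in p1s:
            for q2 in p2s:
                d = float(np.linalg.norm(q1 - q2))
                if best is None or d < best[0]:
                    best = (d, q1, q2)
    _, x1, x2 = best
    d1, _ = vec_to_egg(x1, e2)
    d2, _ = vec_to_egg(x2, e1)
    denom = max(abs(d1), abs(d2), 1e-300)
    discrepancy = abs(d1 - d2) / denom
    return x1, x2, discrepancy


def _polish_disjoint(x1: np.ndarray, e1: Spheroid, e2: Spheroid,
                     max_iter: int = 80, tol: float = 1e-12):
    """Alternating nearest-point projection between two disjoint spheroids."""
    prev = np.inf
    f1 = x1
    for _ in range(max_iter):
        d2, f2 = vec_to_egg(f1, e2)
        d1, f1 = vec_to_egg(f2, e1)
        d = float(np.linalg.norm(f1 - f2))
        if abs(prev - d) < tol:
            break
        prev = d
    return f1, f2


def _penetration(x1: np.ndarray, e1: Spheroid, e2: Spheroid):
    """Deepest-point refinement for overlapping spheroids.

    Minimises the signed distance to ``e2`` over the surface of ``e1``,
    parametrised by spherical angles, starting from the search candidate.
    """
    u1, u2, u3 = _octant_frame(e1)
    b, a = e1.semi_transverse, e1.semi_axial

    def surf(th, ph):
        st = math.sin(th)
        return (e1.center + b * st * math.cos(ph) * u1
                + b * st * math.sin(ph) * u2 + a * math.cos(th) * u3)

    q = x1 - e1.center
    z = float(np.dot(q, u3)) / a
    z = min(1.0, max(-1.0, z))
    th0 = math.acos(z)
    ph0 = math.atan2(float(np.dot(q, u2)), float(np.dot(q, u1)))
    res = minimize(lambda t: vec_to_egg(surf(t[0], t[1]), e2)[0],
                   x0=[th0, ph0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 400})
    p1 = surf(res.x[0], res.x[1])
    d, p2 = vec_to_egg(p1, e2)
    return float(res.fun), p1, p2


def _support(e: Spheroid, n: np.ndarray) -> float:
    """Support extent of a spheroid along unit direction ``n``."""
    ca = float(np.dot(n, e.axis))
    return math.sqrt(e.semi_axial ** 2 * ca * ca
                     + e.semi_transverse ** 2 * (1.0 - ca * ca))


def _containment_gap(inner: Spheroid, outer: Spheroid):
    """Negative gap for a spheroid whose centre lies inside another.

    Extends the sphere-sphere convention (gap = d - Ra - Rb) continuously:
    the centre's signed distance to the outer surface less the inner body's
    support extent toward that surface.  Exact in the sphere limit.
    """
    d_c, foot = vec_to_egg(inner.center, outer)
    n = _unit(foot - inner.center, fallback=_any_perpendicular(outer.axis))
    h = _support(inner, n)
    return d_c - h, inner.center + h * n, foot, n


def _spheroid_key(e: Spheroid) -> tuple:
    return (round(float(e.center[0]), 12), round(float(e.center[1]), 12),
            round(float(e.center[2]), 12), round(float(e.axis[0]), 12),
            round(float(e.axis[1]), 12), round(float(e.axis[2]), 12),
            round(e.semi_axial, 12), round(e.semi_transverse, 12))


def contact_spheroid_spheroid(e1: Spheroid, e2: Spheroid) -> Contact:
    """Contact between two spheroids via the quad-section search.

    The raw search candidates are polished by alternating nearest-point
    projection (the natural fixed point of the vec_to_egg validation step),
    which converges to the true common normal for disjoint convex bodies.
    The pair is evaluated in a deterministic canonical order so the gap is
    exactly symmetric under argument exchange.
    """
    swapped = _spheroid_key(e2) < _spheroid_key(e1)
    a, b = (e2, e1) if swapped else (e1, e2)

    x1, x2, _ = spheroid_contact_search(a, b)
    # The signed minimum over a's surface of the distance to b decides the
    # branch: it equals the gap for disjoint bodies and the (negative)
    # penetration depth for overlapping ones.  Two starts guard against the
    # quad-section candidate sitting away from a shallow crossing.
    starts = [x1]
    if float(np.linalg.norm(b.center - a.center)) > 1e-9:
        starts.append(radial_project(b.center - a.center + a.center, a))
    pen, pp1, pp2 = min((_penetration(s, a, b) for s in starts),
                        key=lambda r: r[0])
    # Full containment leaves every surface-surface distance positive; the
    # centre-inside test catches it.
    contain = []
    if a.implicit(b.center) < 0.0:
        contain.append(_containment_gap(b, a))
    if b.implicit(a.center) < 0.0:
        g, pb, pa, n = _containment_gap(a, b)
        contain.append((g, pa, pb, -n))
    if contain:
        g, pb, pa, n = min(contain, key=lambda r: r[0])
        if g < pen or pen < 0.0:
            if pen < g:
                n2 = _unit(pp1 - pp2, fallback=_any_perpendicular(a.axis))
                contact = Contact(pen, pp1, pp2, n2)
            else:
                contact = Contact(g, pa, pb, n)
            return contact.flipped() if swapped else contact
    if pen >= 0.0:
        best = None
        for s in (x1, pp1):
            f1, f2 = _polish_disjoint(s, a, b)
            d = float(np.linalg.norm(f1 - f2))
            if best is None or d < best[0]:
                best = (d, f1, f2)
        gap, p1, p2 = best
        gap = min(gap, pen)      # the signed minimum is an upper bound
        n = _unit(p2 - p1, fallback=_any_perpendicular(a.axis))
        contact = Contact(gap, p1, p2, n)
    else:
        n = _unit(pp1 - pp2, fallback=_any_perpendicular(a.axis))
        contact = Contact(pen, pp1, pp2, n)
    return contact.flipped() if swapped else contact


# ---------------------------------------------------------------------------
# dispatch

def touch(a: Shape, b: Shape) -> Contact:
    """Signed surface gap and contact normal between any two shapes.

    Dispatches on the six possible pair types; ``touch(a, b).gap ==
    touch(b, a).gap`` with the normal reversed.
    """
    if isinstance(a, Sphere):
        if isinstance(b, Sphere):
            return gap_sphere_sphere(a, b)
        if isinstance(b, Tube):
            return gap_sphere_tube(a, b)
        if isinstance(b, Spheroid):
            return gap_sphere_spheroid(a, b)
    elif isinstance(a, Tube):
        if isinstance(b, Sphere):
            return gap_sphere_tube(b, a).flipped()
        if isinstance(b, Tube):
            return gap_tube_tube(a, b)
        if isinstance(b, Spheroid):
            return gap_tube_spheroid(a, b)
    elif isinstance(a, Spheroid):
        if isinstance(b, Sphere):
            return gap_sphere_spheroid(b, a).flipped()
        if isinstance(b, Tube):
            return gap_tube_spheroid(b, a).flipped()
        if isinstance(b, Spheroid):
            return contact_spheroid_spheroid(a, b)
    raise TypeError(f"unknown shape kinds: {type(a).__name__}, {type(b).__name__}")
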