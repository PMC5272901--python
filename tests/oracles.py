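"""Independent geometric oracles for the test suite.

Everything here is deliberately built on dense sampling plus generic
numerical minimisation (scipy) over surface parametrisations, sharing no
code path with the library's analytic/bisection contact routines.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from hiersim.shapes import Sphere, Spheroid, Tube


def frame_of(e: Spheroid):
    u3 = np.asarray(e.axis, dtype=float)
    t = np.array([1.0, 0.0, 0.0])
    u1 = t - np.dot(t, u3) * u3
    if np.linalg.norm(u1) < 1e-8:
        u1 = np.array([0.0, 1.0, 0.0]) - u3[1] * u3
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(u3, u1)
    return u1, u2, u3


def spheroid_surface(e: Spheroid, th, ph):
    """Surface point(s) at spherical parameters (vectorised)."""
    u1, u2, u3 = frame_of(e)
    th = np.asarray(th, dtype=float)
    ph = np.asarray(ph, dtype=float)
    st = np.sin(th)
    out = (e.center
           + e.semi_transverse * (st * np.cos(ph))[..., None] * u1
           + e.semi_transverse * (st * np.sin(ph))[..., None] * u2
           + e.semi_axial * np.cos(th)[..., None] * u3)
    return out


def _surface_grid(e: Spheroid, nth=48, nph=96):
    th = np.linspace(0.0, math.pi, nth)
    ph = np.linspace(0.0, 2.0 * math.pi, nph, endpoint=False)
    T, P = np.meshgrid(th, ph, indexing="ij")
    pts = spheroid_surface(e, T.ravel(), P.ravel())
    return pts, np.column_stack([T.ravel(), P.ravel()])


def point_in_sphere(p, s: Sphere) -> bool:
    return np.linalg.norm(np.asarray(p) - s.center) < s.radius


def point_in_tube(p, t: Tube) -> bool:
    p = np.asarray(p, dtype=float)
    ab = t.end_b - t.end_a
    denom = float(np.dot(ab, ab))
    s = float(np.dot(p - t.end_a, ab)) / denom if denom > 0 else 0.0
    s = min(1.0, max(0.0, s))
    return np.linalg.norm(p - (t.end_a + s * ab)) < t.radius


def point_in_spheroid(p, e: Spheroid) -> bool:
    q = np.asarray(p, dtype=float) - e.center
    v = float(np.dot(q, e.axis))
    usq = float(np.dot(q, q)) - v * v
    return (usq / e.semi_transverse ** 2 + v * v / e.semi_axial ** 2) < 1.0


def point_inside(p, shape) -> bool:
    if isinstance(shape, Sphere):
        return point_in_sphere(p, shape)
    if isinstance(shape, Tube):
        return point_in_tube(p, shape)
    return point_in_spheroid(p, shape)


def oracle_point_spheroid(p, e: Spheroid, nth=64, nph=128):
    """Signed distance from a point to a spheroid surface by dense surface
    sampling plus Nelder-Mead refinement."""
    p = np.asarray(p, dtype=float)
    pts, angles = _surface_grid(e, nth, nph)
    d = np.linalg.norm(pts - p, axis=1)
    k = int(np.argmin(d))
    res = minimize(lambda x: np.linalg.norm(spheroid_surface(e, x[0], x[1]) - p),
                   angles[k], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 600})
    dist = float(res.fun)
    return -dist if point_in_spheroid(p, e) else dist


def oracle_gap_sphere_tube(s: Sphere, t: Tube, n=20001):
    """Minimum distance over a densely sampled axis, less the joint radii."""
    ts = np.linspace(0.0, 1.0, n)
    axis_pts = t.end_a + ts[:, None] * (t.end_b - t.end_a)
    d = np.linalg.norm(axis_pts - s.center, axis=1)
    return float(d.min()) - (s.radius + t.radius)


def oracle_gap_tube_tube(t1: Tube, t2: Tube, n=301):
    """Dense double sampling of both axes plus 2-D refinement."""
    s = np.linspace(0.0, 1.0, n)
    a = t1.end_a + s[:, None] * (t1.end_b - t1.end_a)
    b = t2.end_a + s[:, None] * (t2.end_b - t2.end_a)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)

    def fun(x):
        pa = t1.end_a + min(1.0, max(0.0, x[0])) * (t1.end_b - t1.end_a)
        pb = t2.end_a + min(1.0, max(0.0, x[1])) * (t2.end_b - t2.end_a)
        return float(np.linalg.norm(pa - pb))

    res = minimize(fun, [s[i], s[j]], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14})
    return float(res.fun) - (t1.radius + t2.radius)


def oracle_gap_sphere_spheroid(s: Sphere, e: Spheroid):
    return oracle_point_spheroid(s.center, e) - s.radius


def oracle_gap_tube_spheroid(t: Tube, e: Spheroid, naxis=160, nth=32, nph=64):
    """Joint minimisation over axis parameter and surface angles."""
    ts = np.linspace(0.0, 1.0, naxis)
    axis_pts = t.end_a + ts[:, None] * (t.end_b - t.end_a)
    surf, angles = _surface_grid(e, nth, nph)
    d = np.linalg.norm(axis_pts[:, None, :] - surf[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)

    def fun(x):
        pa = t.end_a + min(1.0, max(0.0, x[0])) * (t.end_b - t.end_a)
        pb = spheroid_surface(e, x[1], x[2])
        return float(np.linalg.norm(pa - pb))

    res = minimize(fun, [ts[i], angles[j][0], angles[j][1]],
                   method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 1200})
    return float(res.fun) - t.radius


def oracle_gap_spheroid_spheroid(e1: Spheroid, e2: Spheroid, nth=24, nph=48):
    """Constrained minimisation of |x1 - x2| over both surfaces."""
    p1, a1 = _surface_grid(e1, nth, nph)
    p2, a2 = _surface_grid(e2, nth, nph)
    d = np.linalg.norm(p1[:, None, :] - p2[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)

    def fun(x):
        return float(np.linalg.norm(spheroid_surface(e1, x[0], x[1])
                                    - spheroid_surface(e2, x[2], x[3])))

    res = minimize(fun, np.concatenate([a1[i], a2[j]]), method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14,
                            "maxiter": 2500, "maxfev": 5000})
    return float(res.fun)


def overlap_by_sampling(a, b, rng, n=4000) -> bool:
    """Solid inter-penetration test: any sampled surface point of one body
    strictly inside the other (plus mutual centre containment)."""
    def surface_samples(shape, m):
        u = rng.normal(size=(m, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        if isinstance(shape, Sphere):
            return shape.center + shape.radius * u
        if isinstance(shape, Tube):
            s = rng.uniform(0.0, 1.0, m)
            axis_pts = shape.end_a + s[:, None] * (shape.end_b - shape.end_a)
            return axis_pts + shape.radius * u
        th = np.arccos(rng.uniform(-1, 1, m))
        ph = rng.uniform(0, 2 * math.pi, m)
        return spheroid_surface(shape, th, ph)

    center_a = a.center if not isinstance(a, Tube) else a.center
    if point_inside(center_a, b) or point_inside(b.center, a):
        return True
    sa = surface_samples(a, n)
    sb = surface_samples(b, n)
    return (any(point_inside(p, b) for p in sa)
            or any(point_inside(p, a) for p in sb))


def quaternion_rmsd(x, y) -> float:
    """Optimal-superposition RMSD via the quaternion eigenvalue method
    (independent of the SVD route)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sxx = xc.T @ yc
    sx, sy, sz = sxx[0], sxx[1], sxx[2]
    k = np.array([
        [sx[0] + sy[1] + sz[2], sy[2] - sz[1], sz[0] - sx[2], sx[1] - sy[0]],
        [sy[2] - sz[1], sx[0] - sy[1] - sz[2], sx[1] + sy[0], sz[0] + sx[2]],
        [sz[0] - sx[2], sx[1] + sy[0], -sx[0] + sy[1] - sz[2], sy[2] + sz[1]],
        [sx[1] - sy[0], sz[0] + sx[2], sy[2] + sz[1], -sx[0] - sy[1] + sz[2]],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = ((xc * xc).sum() + (yc * yc).sum() - 2.0 * lam) / len(x)
    return math.sqrt(max(0.0, e0))
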