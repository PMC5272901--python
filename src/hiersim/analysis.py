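"""Measurement utilities: superposition RMSD, domain distortion tables,
clash census by kinship, and score-vs-RMSD exports.

RMSD values are reported in Angstrom regardless of the internal unit
convention; pass the appropriate units-per-Angstrom factor when the
coordinates are internal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants
from .hierarchy import Node, leaves

__all__ = ["kabsch_rmsd", "RmsdSummary", "domain_rmsd_table", "clash_census",
           "export_score_rmsd", "spheroid_contact_validation"]


def spheroid_contact_validation(n_pairs: int = 1000, seed: int = 0):
    """Self-consistency audit of the spheroid-spheroid contact search.

    Generates random non-overlapping spheroid pairs (mixed prolate and
    oblate, semi-axes in [0.5, 3], random poses), runs the octant
    triangulation quad-section contact search (depth 3, 9-point refinement)
    and validates each candidate contact point against the opposing surface
    with the exact point-to-spheroid distance.  Returns the array of
    relative disagreements between the two validation distances, one per
    pair -- the figure of merit the search reports on itself.
    """
    from .shapes import Spheroid, contact_spheroid_spheroid, \
        spheroid_contact_search

    rng = np.random.default_rng(seed)

    def rand_spheroid(center):
        ax = rng.normal(size=3)
        ax /= np.linalg.norm(ax)
        a, b = rng.uniform(0.5, 3.0, 2)
        return Spheroid(center, ax, float(a), float(b))

    out = np.empty(n_pairs)
    done = 0
    while done < n_pairs:
        e1 = rand_spheroid(rng.uniform(-1, 1, 3))
        e2 = rand_spheroid(rng.uniform(-1, 1, 3) + rng.normal(scale=4, size=3))
        if contact_spheroid_spheroid(e1, e2).gap <= 0.05:
            continue          # guaranteed positive gap only
        out[done] = spheroid_contact_search(e1, e2)[2]
        done += 1
    return out


def kabsch_rmsd(x, y) -> float:
    """Least-squares optimal-superposition RMSD of two matched point sets.

    Centroids are removed and the optimal proper rotation (det +1) found by
    singular value decomposition of the covariance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("point sets must match and contain >= 3 points")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    e = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(e) @ u.T
    diff = yc - xc @ rot.T
    return float(np.sqrt((diff * diff).sum() / len(x)))


@dataclass
class RmsdSummary:
    min: float
    mean: float
    max: float


def domain_rmsd_table(before, after, domains, exclude_termini: int = 5,
                      units_per_angstrom: float = constants.PROTEIN_UNITS_PER_ANGSTROM
                      ) -> RmsdSummary:
    """Pairwise distortion of equivalent domains before vs after an event.

    Every domain of the starting structure is superposed on every domain of
    the final structure (all domains share one decomposition, so any pair
    is comparable) with the ``exclude_termini`` linking residues trimmed
    from each end; returns the smallest, mean and largest RMSD in Angstrom.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    segs_b, segs_a = [], []
    for d0, d1 in domains:
        s0 = d0 + exclude_termini
        s1 = d1 - exclude_termini
        if s1 - s0 < 3:
            s0, s1 = d0, d1
        segs_b.append(before[s0:s1])
        segs_a.append(after[s0:s1])
    vals = []
    for xb in segs_b:
        for ya in segs_a:
            if len(xb) == len(ya):
                vals.append(kabsch_rmsd(xb, ya) / units_per_angstrom)
    vals = np.array(vals)
    return RmsdSummary(float(vals.min()), float(vals.mean()), float(vals.max()))


def _lca_depth(a: Node, b: Node) -> int:
    """Tree distance from the leaves up to the lowest common ancestor:
    1 = same parent (cousins), 2 = same grandparent, ..."""
    ancestors = {}
    n, d = a, 0
    while n is not None:
        ancestors[n.id] = d
        n, d = n.parent, d + 1
    n, d = b, 0
    while n is not None:
        if n.id in ancestors:
            return max(ancestors[n.id], d)
        n, d = n.parent, d + 1
    return -1


def clash_census(root: Node) -> dict[int, int]:
    """Count atomic bump overlaps bucketed by kinship level.

    Exhaustive leaf-pair scan (diagnostic); bonded/linked pairs excluded.
    Bucket 1 holds same-parent clashes, 2 same-grandparent, and so on.
    """
    lv = leaves(root)
    p = np.array([n.center for n in lv])
    r = np.array([n.bump_radius for n in lv])
    d = np.sqrt(((p[:, None, :] - p[None, :, :]) ** 2).sum(2))
    g = d - (r[:, None] + r[None, :])
    out: dict[int, int] = {}
    ii, jj = np.where(g < 0)
    for i, j in zip(ii, jj):
        if i >= j:
            continue
        a, b = lv[i], lv[j]
        if a.exempt_with(b):
            continue
        k = _lca_depth(a, b)
        out[k] = out.get(k, 0) + 1
    return out


def export_score_rmsd(rows, path) -> None:
    """Write (model id, constraint score, RMSD) rows to CSV."""
    import pandas as pd
    df = pd.DataFrame(rows, columns=["model", "score", "rmsd"])
    df.to_csv(path, index=False)
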