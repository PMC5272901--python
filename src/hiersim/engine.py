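"""The simulation loop and its driver protocols.

A cycle applies, in order: user-driver displacements, the hierarchical
collision pass, containment, bond refinement, link refinement, centroid
synchronisation and (periodically) axis realignment.  With no driver and a
relaxed model the engine does nothing -- all motion is supplied by drivers.
Two drivers reproduce the canonical experiments: engineered collisions
(a constant approach displacement propelling two bodies into each other
with a lateral impact offset) and distance-constraint satisfaction (either
progressive introduction in strength order, or top-k introduction with
stochastic annealing and gradual culling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bonds import adjust_pair, refine_bonds, refine_links
from .bumper import bump_in
from .hierarchy import (Node, ParamSet, iter_nodes, leaves, move_node,
                        realign_axis, rotate_node, sync_centers)
from .keeper import apply_keeper
from .shapes import Sphere, Tube, Spheroid

__all__ = [
    "Constraint", "RunConfig", "step", "run", "run_collision",
    "CollisionRecord", "constraint_driver_progressive",
    "constraint_driver_cull", "constraint_score", "indexed_leaves",
]


@dataclass
class Constraint:
    """A distance restraint between two leaf indices.

    ``strength`` is the prior probability/score of the restraint being
    correct; culled constraints never reactivate.
    """
    i: int
    j: int
    target: float
    strength: float = 1.0
    live: bool = True
    within_stem: bool = False


@dataclass
class RunConfig:
    params: ParamSet
    n_steps: int = 100
    seed: int = 0
    slow_factor: float = 1.0
    sync_every: int = 1
    realign_every: int = 10
    realign_method: str = "termini"


def indexed_leaves(root: Node) -> list[Node]:
    """Leaves ordered by their builder-assigned sequence label (falling
    back to tree order for unlabelled leaves)."""
    lv = leaves(root)
    if all(isinstance(n.label, int) for n in lv):
        return sorted(lv, key=lambda n: n.label)
    return lv


def _effective_params(cfg: RunConfig) -> ParamSet:
    if cfg.slow_factor == 1.0:
        return cfg.params
    return cfg.params.scaled(1.0 / cfg.slow_factor)


def step(model: Node, cfg: RunConfig, driver=None, step_index: int = 0,
         rng: np.random.Generator | None = None,
         params_eff: ParamSet | None = None) -> None:
    """One engine cycle.  ``driver(model, step_index, rng)`` runs first."""
    if params_eff is None:
        params_eff = _effective_params(cfg)
    if driver is not None:
        driver(model, step_index, rng)
    bump_in(model, params_eff)
    apply_keeper(model, params_eff)
    refine_bonds(model, params_eff)
    refine_links(model, params_eff)
    if cfg.sync_every and step_index % cfg.sync_every == 0:
        sync_centers(model)
    if cfg.realign_every and step_index % cfg.realign_every == cfg.realign_every - 1:
        for n in iter_nodes(model):
            if n.children and not isinstance(n.shape, Sphere):
                realign_axis(n, cfg.realign_method)


def run(model: Node, cfg: RunConfig, driver=None) -> Node:
    """Run ``cfg.n_steps`` cycles (times the slow factor) with a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    params_eff = _effective_params(cfg)
    total = int(round(cfg.n_steps * cfg.slow_factor))
    for t in range(total):
        step(model, cfg, driver, t, rng, params_eff)
    return model


# ---------------------------------------------------------------------------
# engineered collisions

def _leaf_arrays(body: Node):
    lv = leaves(body)
    return (np.array([n.center for n in lv]),
            np.array([n.bump_radius for n in lv]), lv)


#: Overlaps shallower than this are rounding noise (e.g. from rigid
#: rotations of an exactly-touching packing), not steric clashes.
CLASH_TOL = 1e-9


def _clash_counts(body_a: Node, body_b: Node) -> tuple[int, int, int]:
    """(cross, intra_a, intra_b) atomic bump-overlap counts, bonded pairs
    excluded, by flat scans."""
    pa, ra, la = _leaf_arrays(body_a)
    pb, rb, lb = _leaf_arrays(body_b)

    def intra(p, r, ln):
        d = np.sqrt(((p[:, None, :] - p[None, :, :]) ** 2).sum(2))
        g = d - (r[:, None] + r[None, :])
        ii, jj = np.where(g < -CLASH_TOL)
        return sum(1 for i, j in zip(ii, jj)
                   if i < j and not ln[i].exempt_with(ln[j]))

    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(2))
    g = d - (ra[:, None] + rb[None, :])
    cross = int((g < -CLASH_TOL).sum())
    return cross, intra(pa, ra, la), intra(pb, rb, lb)


@dataclass
class CollisionRecord:
    cross: list = field(default_factory=list)
    intra_a: list = field(default_factory=list)
    intra_b: list = field(default_factory=list)
    trajectory: list = field(default_factory=list)

    @property
    def max_cross(self) -> int:
        return max(self.cross) if self.cross else 0


def run_collision(stage: Node, a: Node, b: Node, cfg: RunConfig,
                  approach_speed: float | None = None,
                  approach_axis=None,
                  randomize_orientation: bool = True,
                  record_trajectory: bool = False,
                  record_every: int = 1) -> CollisionRecord:
    """Propel two sibling bodies into (and past) each other.

    A constant displacement is applied to each body along the approach axis
    every cycle; the lateral impact offset is part of the starting
    placement.  Per-cycle inter- and intra-body atomic clash counts are
    recorded after the driver displacement, before the corrective passes.
    """
    rng = np.random.default_rng(cfg.seed)
    if approach_axis is None:
        d = b.center - a.center
        approach_axis = d / np.linalg.norm(d)
        # strip the lateral offset: approach along the dominant component
        k = int(np.argmax(np.abs(approach_axis)))
        approach_axis = np.zeros(3)
        approach_axis[k] = 1.0 if (b.center - a.center)[k] > 0 else -1.0
    if approach_speed is None:
        ext = max(_body_radius(a), _body_radius(b))
        approach_speed = ext / 10.0
    approach_speed /= cfg.slow_factor
    if randomize_orientation:
        from scipy.spatial.transform import Rotation
        for body in (a, b):
            rot = Rotation.random(rng=rng).as_matrix()
            rotate_node(body, rot, body.center)

    rec = CollisionRecord()
    params_eff = _effective_params(cfg)
    total = int(round(cfg.n_steps * cfg.slow_factor))
    for t in range(total):
        move_node(a, +approach_speed * approach_axis)
        move_node(b, -approach_speed * approach_axis)
        cross, ia, ib = _clash_counts(a, b)
        rec.cross.append(cross)
        rec.intra_a.append(ia)
        rec.intra_b.append(ib)
        step(stage, cfg, None, t, rng, params_eff)
        if record_trajectory and t % record_every == 0:
            rec.trajectory.append(np.array([n.center for n in leaves(stage)]))
    return rec


def _body_radius(n: Node) -> float:
    s = n.shape
    if isinstance(s, Sphere):
        return s.radius
    if isinstance(s, Tube):
        return 0.5 * s.length + s.radius
    return max(s.semi_axial, s.semi_transverse)


# ---------------------------------------------------------------------------
# distance-constraint satisfaction

def _constraint_dist(lv: list[Node], c: Constraint) -> float:
    return float(np.linalg.norm(lv[c.j].center - lv[c.i].center))


def _constraint_step(cfg: RunConfig, lv: list[Node]) -> float:
    level = max(n.level for n in lv)
    bond = cfg.params.at(level).bond
    return bond if bond else 0.05


def constraint_driver_progressive(model: Node, constraints, cfg: RunConfig,
                                  activate_every: int = 5):
    """Introduce constraints progressively in order of strength.

    A constraint is activated only if it currently lies within twice its
    target distance, and is discarded if it ever strays beyond that bound
    afterwards; active constraints pull their leaf pair toward the target
    each cycle.  Returns the list of retained constraints.
    """
    lv = indexed_leaves(model)
    kick = _constraint_step(cfg, lv)
    pending = sorted([c for c in constraints if c.live],
                     key=lambda c: -c.strength)
    active: list[Constraint] = []
    rng = np.random.default_rng(cfg.seed)
    params_eff = _effective_params(cfg)
    total = int(round(cfg.n_steps * cfg.slow_factor))

    def driver(m, t, r):
        if pending and (t % activate_every == 0):
            c = pending.pop(0)
            if _constraint_dist(lv, c) <= 2.0 * c.target:
                active.append(c)
            else:
                c.live = False
        for c in list(active):
            if _constraint_dist(lv, c) > 2.0 * c.target:
                c.live = False
                active.remove(c)
                continue
            adjust_pair(lv[c.i], lv[c.j], c.target, kick)

    for t in range(total):
        step(model, cfg, driver, t, rng, params_eff)
    # drain any constraints not yet activated
    while pending:
        c = pending.pop(0)
        if _constraint_dist(lv, c) <= 2.0 * c.target:
            active.append(c)
        else:
            c.live = False
    return active


def constraint_driver_cull(model: Node, constraints, cfg: RunConfig,
                           k: int = 50, containment_fraction: float = 0.4,
                           cull_every: int = 50,
                           anneal_amplitude: float | None = None,
                           stem_penalty: float = 3.0,
                           cull_floor: float = 0.5):
    """Introduce the top-k constraints at once; anneal and gradually cull.

    Random displacements with linearly decaying amplitude are applied to
    the stem-loop level objects; after the containment phase one constraint
    is periodically removed from those that have failed to approach their
    target (fractional violation above ``cull_floor``), chosen with
    probability proportional to its current violation, inversely to its
    strength, and biased against constraints within a stem-loop.
    Constraints that have approached their target are never culled.
    Returns the surviving constraints.
    """
    lv = indexed_leaves(model)
    kick = _constraint_step(cfg, lv)
    ranked = sorted([c for c in constraints if c.live],
                    key=lambda c: -c.strength)
    active = ranked[:min(k, len(ranked))]
    movers = [n for n in model.children if n.children]
    if anneal_amplitude is None:
        anneal_amplitude = 0.5
    rng = np.random.default_rng(cfg.seed)
    params_eff = _effective_params(cfg)
    total = int(round(cfg.n_steps * cfg.slow_factor))
    contain_until = int(containment_fraction * total)

    def violation(c):
        d = _constraint_dist(lv, c)
        return max(0.0, d - c.target) / c.target

    def driver(m, t, r):
        amp = anneal_amplitude * max(0.0, 1.0 - t / max(total - 1, 1))
        if amp > 0:
            for node in movers:
                v = r.normal(size=3)
                nv = np.linalg.norm(v)
                if nv > 0:
                    move_node(node, amp / cfg.slow_factor * v / nv)
        for c in active:
            adjust_pair(lv[c.i], lv[c.j], c.target, kick)
        if t > contain_until and cull_every and t % cull_every == 0 \
                and len(active) > 1:
            v = np.array([violation(c) for c in active])
            w = np.where(v > cull_floor, v, 0.0) \
                * np.array([(1.0 / max(c.strength, 1e-9))
                            * (stem_penalty if c.within_stem else 1.0)
                            for c in active])
            if w.sum() > 1e-12:
                idx = int(r.choice(len(active), p=w / w.sum()))
                active[idx].live = False
                active.pop(idx)

    for t in range(total):
        step(model, cfg, driver, t, rng, params_eff)
    return active


def constraint_score(model: Node, constraints) -> float:
    """Strength-weighted satisfaction score over the evaluated set:
    sum of strength * max(0, 1 - |d - target| / target); higher is better,
    an exactly satisfied set scores the summed strength."""
    lv = indexed_leaves(model)
    s = 0.0
    for c in constraints:
        d = _constraint_dist(lv, c)
        s += c.strength * max(0.0, 1.0 - abs(d - c.target) / c.target)
    return s
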