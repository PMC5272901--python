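"""Bond-length maintenance and breakable links.

Bonds are permanent topology; every pass pushes each bonded pair
symmetrically toward its assigned length by the per-level ``bond`` step.
Links follow the same refinement but can break: a link stretched beyond its
maximum extension (50% over target by default) is destroyed for the rest of
the run and removed from the collision exemptions.  Local links are preset
for standard secondary structures (helix i,i+3 and i,i+4; strand i-1,i+1);
non-local sheet pairings are user input.
"""

from __future__ import annotations

import numpy as np

from . import constants
from .hierarchy import Node, ParamSet, iter_nodes, move_node
from .shapes import _unit, TIE_BREAK

__all__ = ["adjust_pair", "refine_bonds", "refine_links", "preset_links"]


def adjust_pair(a: Node, b: Node, target: float, step: float) -> float:
    """Move two nodes symmetrically toward separation ``target``.

    Caps at the residual so the pair never overshoots; returns the applied
    displacement (signed: positive = pulled together).
    """
    if step <= 0.0:
        return 0.0
    d = b.center - a.center
    dist = float(np.linalg.norm(d))
    delta = dist - target
    if delta == 0.0:
        return 0.0
    n = _unit(d, fallback=TIE_BREAK)
    mv = min(step, abs(delta))
    if delta > 0:            # too long: pull together
        move_node(a, +0.5 * mv * n)
        move_node(b, -0.5 * mv * n)
        return mv
    move_node(a, -0.5 * mv * n)
    move_node(b, +0.5 * mv * n)
    return -mv


def refine_bonds(root: Node, params: ParamSet) -> None:
    """One pass pushing every bonded pair toward its assigned length.

    Basepair ``stack`` bonds act on tube centres (the stacking separation);
    ``segment`` bonds hold duplex segments end-to-end at the
    helix-continuation distance.  Both are ordinary centre-centre targets
    here because tube centres track the relevant anchor points.
    """
    for n in iter_nodes(root):
        rec = params.at(n.level)
        step = rec.bond
        if step is None or step <= 0.0:
            continue
        for bond in n.bonds:
            adjust_pair(n, bond.partner, bond.target, step)


def refine_links(root: Node, params: ParamSet) -> int:
    """One pass over live links: tighten toward target, break the
    over-stretched.  Returns the number of links destroyed."""
    broken = 0
    for n in iter_nodes(root):
        rec = params.at(n.level)
        step = rec.bond if rec.bond is not None else 0.0
        for lk in n.links:
            if not lk.live:
                continue
            dist = float(np.linalg.norm(lk.partner.center - n.center))
            if dist > lk.max_extension * lk.target:
                n.break_link(lk)
                broken += 1
                continue
            if step > 0.0:
                adjust_pair(n, lk.partner, lk.target, step)
    return broken


def preset_links(residues: list[Node], sse: str,
                 units_per_angstrom: float = constants.PROTEIN_UNITS_PER_ANGSTROM
                 ) -> int:
    """Create the automatic secondary-structure links.

    Alpha-helix runs link (i, i+3) and (i, i+4); beta-strand runs link
    (i-1, i+1).  Non-local links between sheet strands must be supplied by
    the user.  Returns the number of links created.
    """
    if len(residues) != len(sse):
        raise ValueError("residue list and secondary-structure string differ")
    t33 = constants.HELIX_I_I3_ANGSTROM * units_per_angstrom
    t44 = constants.HELIX_I_I4_ANGSTROM * units_per_angstrom
    t22 = constants.STRAND_I_I2_ANGSTROM * units_per_angstrom
    made = 0
    i = 0
    n = len(sse)
    while i < n:
        ss = sse[i]
        j = i
        while j < n and sse[j] == ss:
            j += 1
        run = range(i, j)
        if ss == "H":
            for k in run:
                if k + 3 < j:
                    residues[k].link_to(residues[k + 3], t33)
                    made += 1
                if k + 4 < j:
                    residues[k].link_to(residues[k + 4], t44)
                    made += 1
        elif ss == "E":
            for k in run:
                if k + 2 < j:
                    residues[k].link_to(residues[k + 2], t22)
                    made += 1
        i = j
    return made
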