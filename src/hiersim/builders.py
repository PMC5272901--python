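"""Construct hierarchies from molecules and synthetic generators.

Builders translate molecular inputs (Ca traces, phosphate traces, secondary
structure, base pairs) or synthetic recipes (Hilbert-curve chains, ideal
helices, cloverleaf layouts) into the nested container tree the simulation
engine operates on.  All outputs are in internal length units; conversion
conventions live in :mod:`hiersim.constants`.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from . import constants
from .bonds import preset_links
from .hierarchy import Node, fit_container, leaves
from .shapes import Sphere, Spheroid, Tube, _unit

__all__ = [
    "hilbert_curve", "hilbert_chain", "make_crash_pair",
    "build_protein", "build_rna", "pairs_to_stems", "layout_cloverleaf",
    "build_tm_bundle", "read_trace", "write_trace", "ideal_helix",
]


# ---------------------------------------------------------------------------
# Hilbert curve (3-D, Skilling transpose algorithm)

def _d2xyz(d: int, order: int) -> list[int]:
    x = [0, 0, 0]
    for k in range(order):
        trip = (d >> (3 * (order - 1 - k))) & 7
        pos = order - 1 - k
        x[0] |= ((trip >> 2) & 1) << pos
        x[1] |= ((trip >> 1) & 1) << pos
        x[2] |= (trip & 1) << pos
    # Gray decode
    t = x[2] >> 1
    for i in (2, 1):
        x[i] ^= x[i - 1]
    x[0] ^= t
    # Undo excess work
    n = 2 << (order - 1)
    q = 2
    while q != n:
        p = q - 1
        for i in (2, 1, 0):
            if x[i] & q:
                x[0] ^= p
            else:
                t = (x[0] ^ x[i]) & p
                x[0] ^= t
                x[i] ^= t
        q <<= 1
    return x


def hilbert_curve(order: int) -> np.ndarray:
    """Integer lattice coordinates of the 3-D Hilbert curve of the given
    order: 8**order points, consecutive points one lattice step apart, and
    every aligned block of 8**k consecutive points confined to a sub-cube
    of side 2**k."""
    if order < 1:
        raise ValueError("order must be >= 1")
    return np.array([_d2xyz(d, order) for d in range(8 ** order)], dtype=float)


def hilbert_chain(levels: int, bond: float = 1.0,
                  container_bump: str = "enclosing",
                  atom_radius: float | None = None,
                  base_level: int = 0,
                  margin_out: float = 1.1) -> Node:
    """A homogeneous test chain: 8**levels atoms on a Hilbert path packaged
    into a hierarchy of spheres with eight children per node.

    ``container_bump`` selects the collision-radius convention:

    * ``"enclosing"`` -- container bump spheres cover their children
      (including the keeper margin band), so the hierarchical bump pass is
      guaranteed to reach every atomic overlap;
    * ``"touching"`` -- container bump radii equal half the spacing between
      consecutive containers, so the packed chain is exactly at steric
      equilibrium (a relaxed fixed-point fixture).

    Shape radii (used by the keeper) always enclose.  Consecutive atoms and
    consecutive containers at every level are bonded at their construction
    distances, so a freshly built chain is at its bonded fixed point.
    """
    if not 1 <= levels <= 4:
        raise ValueError("levels must be in 1..4")
    if container_bump not in ("enclosing", "touching"):
        raise ValueError("container_bump must be 'enclosing' or 'touching'")
    if atom_radius is None:
        atom_radius = bond / 2.0
    pts = hilbert_curve(levels) * bond
    atoms = [Node(Sphere(p, atom_radius), level=base_level + levels,
                  kind="generic") for p in pts]
    for i, at in enumerate(atoms):
        at.label = i
    for a, b in zip(atoms, atoms[1:]):
        a.bond_to(b, bond)

    nodes = atoms
    lv = base_level + levels
    while len(nodes) > 1:
        lv -= 1
        depth = base_level + levels - lv          # 1 at the first grouping
        groups = [nodes[i:i + 8] for i in range(0, len(nodes), 8)]
        parents = []
        for g in groups:
            centroid = np.mean([c.center for c in g], axis=0)
            r_child = max(_radial_extent(c) for c in g)
            maxdist = max(float(np.linalg.norm(c.center - centroid)) for c in g)
            shape_r = maxdist + r_child
            if container_bump == "enclosing":
                bump_r = (margin_out * (shape_r - r_child)
                          + max(c.bump_radius for c in g))
            else:
                bump_r = (2 ** depth) * bond / 2.0
            p = Node(Sphere(centroid, shape_r), level=lv, kind="generic",
                     bump_radius=bump_r)
            for c in g:
                p.add_child(c)
            parents.append(p)
        for a, b in zip(parents, parents[1:]):
            a.bond_to(b, float(np.linalg.norm(b.center - a.center)))
        nodes = parents
    return nodes[0]


def _radial_extent(n: Node) -> float:
    s = n.shape
    if isinstance(s, Sphere):
        return s.radius
    if isinstance(s, Tube):
        return 0.5 * s.length + s.radius
    return max(s.semi_axial, s.semi_transverse)


def make_crash_pair(levels: int, bond: float = 1.0,
                    separation_factor: float = 3.0,
                    impact_fraction: float = 0.5,
                    container_bump: str = "enclosing",
                    shell_padding: float = 1.2):
    """Two identical Hilbert bodies staged for an engineered collision.

    The bodies face each other along x, the second offset laterally by
    ``impact_fraction`` times the container radius from the line of
    approach.  Returns ``(root, body_a, body_b)`` with both bodies siblings
    under a stage root that plays no collision or containment role.

    ``shell_padding`` inflates the outermost shell of each body so the
    shell stands clear of its atoms: with a fully hard/soft shell the
    repulsion then acts before any atomic contact, and atomic contact only
    occurs once soft inter-penetration is allowed to accumulate.
    """
    a = hilbert_chain(levels, bond, container_bump, base_level=1)
    b = hilbert_chain(levels, bond, container_bump, base_level=1)
    for body in (a, b):
        body.shape.radius *= shell_padding
        body.bump_radius *= shell_padding
    radius = a.shape.radius
    d = separation_factor * (2.0 * radius)
    from .hierarchy import move_node
    move_node(a, np.array([-0.5 * d, 0.0, 0.0]) - a.center)
    move_node(b, np.array([+0.5 * d, impact_fraction * radius, 0.0]) - b.center)
    stage = Node(Sphere(np.zeros(3), d + 4 * radius), level=0, kind="generic",
                 bump_radius=1e-9)
    stage.add_child(a)
    stage.add_child(b)
    return stage, a, b


# ---------------------------------------------------------------------------
# proteins

def _sse_runs(sse: str):
    runs = []
    i = 0
    while i < len(sse):
        j = i
        while j < len(sse) and sse[j] == sse[i]:
            j += 1
        runs.append((i, j, sse[i]))
        i = j
    return runs


def build_protein(ca_angstrom, sse: str, domains=None,
                  bump_diameter_angstrom: float = constants.PROTEIN_BUMP_DIAMETER_ANGSTROM,
                  sheet_links=None) -> Node:
    """Build a protein hierarchy from a Ca trace (Angstrom) and per-residue
    secondary structure ({H, E, C}).

    Residues become hard spheres (bump diameter = the minimal allowed
    i,i+2 Ca separation); contiguous secondary-structure runs become tubes
    with preset length:radius ratios; each domain becomes the closest
    symmetric spheroid; multiple domains are enclosed in an envelope
    spheroid.  Helix/strand hydrogen-bond surrogate links are preset;
    ``sheet_links`` may supply user-defined (i, j) strand pairings.
    """
    ca = np.asarray(ca_angstrom, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValueError("ca trace must be (n, 3)")
    if len(ca) != len(sse):
        raise ValueError("trace length and secondary-structure string differ")
    scale = constants.PROTEIN_UNITS_PER_ANGSTROM
    pts = ca * scale
    n = len(pts)
    if domains is None:
        domains = [(0, n)]
    atom_r = 0.5 * bump_diameter_angstrom * scale
    multi = len(domains) > 1
    lv_dom = 1 if multi else 0
    lv_sse = lv_dom + 1
    lv_atom = lv_sse + 1

    residues = [Node(Sphere(p, atom_r), level=lv_atom, kind="protein_atom")
                for p in pts]
    for i, r in enumerate(residues):
        r.label = i
    for a, b in zip(residues, residues[1:]):
        a.bond_to(b, constants.PROTEIN_BOND_UNITS)
    preset_links(residues, sse)
    if sheet_links:
        t = constants.protein_to_internal(constants.STRAND_I_I2_ANGSTROM)
        for i, j in sheet_links:
            residues[i].link_to(residues[j], t)

    kind_map = {"H": "sse_alpha", "E": "sse_beta", "C": "sse_loop"}
    sse_nodes = []
    for i, j, ss in _sse_runs(sse):
        run_pts = pts[i:j]
        centroid = run_pts.mean(axis=0)
        if j - i >= 2:
            axis = _unit(run_pts[-1] - run_pts[0])
            if float(np.linalg.norm(run_pts[-1] - run_pts[0])) < 1e-9:
                axis = np.array([0.0, 0.0, 1.0])
        else:
            axis = np.array([0.0, 0.0, 1.0])
        length = (j - i) * constants.SSE_RISE_ANGSTROM[ss] * scale
        radius = constants.SSE_TUBE_RADIUS_ANGSTROM[ss] * scale
        tube = Tube(centroid - 0.5 * length * axis,
                    centroid + 0.5 * length * axis, radius)
        node = Node(tube, level=lv_sse, kind=kind_map[ss])
        for r in residues[i:j]:
            node.add_child(r)
        sse_nodes.append((i, j, node))

    dom_nodes = []
    for (d0, d1) in domains:
        egg = fit_container(pts[d0:d1], "spheroid", padding=atom_r)
        dn = Node(egg, level=lv_dom, kind="protein_domain")
        dom_nodes.append((d0, d1, dn))
    for i, j, node in sse_nodes:
        mid = 0.5 * (i + j)
        for d0, d1, dn in dom_nodes:
            if d0 <= mid < d1:
                dn.add_child(node)
                break
        else:
            dom_nodes[-1][2].add_child(node)

    if multi:
        env = Node(fit_container(pts, "spheroid", padding=atom_r),
                   level=0, kind="protein_envelope")
        for _, _, dn in dom_nodes:
            env.add_child(dn)
        return env
    return dom_nodes[0][2]


def ideal_helix(n: int, radius_angstrom: float = 2.3,
                rise_angstrom: float = 1.5,
                turn_deg: float = 100.0) -> np.ndarray:
    """Ideal alpha-helix Ca coordinates (Angstrom) along +z."""
    th = np.radians(turn_deg) * np.arange(n)
    return np.column_stack([radius_angstrom * np.cos(th),
                            radius_angstrom * np.sin(th),
                            rise_angstrom * np.arange(n)])


# ---------------------------------------------------------------------------
# nucleic acids

def pairs_to_stems(pairs):
    """Group base pairs into helical stems: maximal runs of nested pairs
    (i, j), (i+1, j-1), ...  Raises if any phosphate appears in two pairs."""
    seen = {}
    norm = []
    for i, j in pairs:
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        for k in (i, j):
            if k in seen:
                raise ValueError(f"phosphate {k} appears in more than one pair")
            seen[k] = True
        norm.append((i, j))
    norm.sort()
    stems = []
    for i, j in norm:
        if stems and stems[-1][-1] == (i - 1, j + 1):
            stems[-1].append((i, j))
        else:
            stems.append([(i, j)])
    return stems


def build_rna(p_coords, pairs, molecule: str = "rna",
              units: str = "internal") -> Node:
    """Build an RNA/DNA hierarchy from a phosphate trace and a base-pair
    list.

    Each base pair becomes a small tube with its two phosphates at the axis
    ends; helical stems become enclosing tubes whose ideal diameter places
    the phosphates on the surface; unpaired runs become weakly confining
    loop tubes; the whole molecule is confined in a container sphere.  For
    DNA, segments are bonded end-to-end so the double helix can run
    continuously ("string of sausages").
    """
    pts = np.asarray(p_coords, dtype=float)
    if units == "angstrom":
        pts = pts * constants.NUCLEIC_UNITS_PER_ANGSTROM
    n = len(pts)
    ideal = constants.DNA_DUPLEX if molecule == "dna" else constants.RNA_DUPLEX
    stems = pairs_to_stems(pairs)
    paired = {k for st in stems for ij in st for k in ij}

    phosphates = [Node(Sphere(p, constants.PHOSPHATE_BUMP_RADIUS),
                       level=3, kind="rna_phosphate") for p in pts]
    for i, ph in enumerate(phosphates):
        ph.label = i
    for a, b in zip(phosphates, phosphates[1:]):
        a.bond_to(b, 1.0)

    root = Node(fit_container(pts, "sphere",
                              padding=constants.PHOSPHATE_BUMP_RADIUS),
                level=0, kind="generic")

    stem_nodes = []
    for st in stems:
        mids = []
        bp_nodes = []
        for (i, j) in st:
            bp = Node(Tube(pts[i], pts[j], constants.BASEPAIR_TUBE_RADIUS),
                      level=2, kind="basepair")
            bp.add_child(phosphates[i])
            bp.add_child(phosphates[j])
            bp_nodes.append(bp)
            mids.append(0.5 * (pts[i] + pts[j]))
        mids = np.asarray(mids)
        if len(mids) >= 2:
            axis = _unit(mids[-1] - mids[0])
            length = float(np.linalg.norm(mids[-1] - mids[0])) + ideal.rise
        else:
            axis = _unit(pts[st[0][1]] - pts[st[0][0]])
            axis = _unit(np.cross(axis, np.array([0.0, 0.0, 1.0])),
                         fallback=np.array([0.0, 0.0, 1.0]))
            length = ideal.rise
        center = mids.mean(axis=0)
        tube = Tube(center - 0.5 * length * axis, center + 0.5 * length * axis,
                    0.5 * ideal.pp_span)
        kind = "dna_segment" if molecule == "dna" else "stemloop"
        sn = Node(tube, level=1, kind=kind)
        for bp in bp_nodes:
            sn.add_child(bp)
        for a, b in zip(bp_nodes, bp_nodes[1:]):
            a.bond_to(b, ideal.rise, kind="stack")
        root.add_child(sn)
        stem_nodes.append(sn)

    if molecule == "dna":
        for a, b in zip(stem_nodes, stem_nodes[1:]):
            a.bond_to(b, 0.5 * (a.shape.length + b.shape.length) + ideal.rise,
                      kind="segment")

    # unpaired runs -> loop objects
    i = 0
    while i < n:
        if i in paired:
            i += 1
            continue
        j = i
        while j < n and j not in paired:
            j += 1
        if j - i >= 2:
            tube = fit_container(pts[i:j], "tube",
                                 padding=constants.PHOSPHATE_BUMP_RADIUS)
            loop = Node(tube, level=1, kind="rna_loop")
            for k in range(i, j):
                loop.add_child(phosphates[k])
            root.add_child(loop)
        else:
            phosphates[i].level = 1
            root.add_child(phosphates[i])
        i = j
    return root


def layout_cloverleaf(pairs, n: int, permutation=None,
                      hub_radius: float = 2.0) -> np.ndarray:
    """Planar cloverleaf starting coordinates for ``n`` phosphates.

    Stems radiate from a hub as straight ladders; hairpin-loop phosphates
    follow an arc around the stem tip; linker phosphates follow arcs around
    the hub.  ``permutation`` reorders the angular slots of the stems (the
    cyclic stem-swap alternative starting layout).  All z coordinates are 0.
    """
    stems = pairs_to_stems(pairs)
    m = len(stems)
    if permutation is None:
        permutation = list(range(m))
    if sorted(permutation) != list(range(m)):
        raise ValueError("permutation must reorder the stems")
    ideal = constants.RNA_DUPLEX
    span = ideal.pp_span
    coords = np.full((n, 3), np.nan)

    angles = {s: 2.0 * math.pi * permutation[s] / max(m, 1) for s in range(m)}
    for s, st in enumerate(stems):
        th = angles[s]
        d = np.array([math.cos(th), math.sin(th), 0.0])
        perp = np.array([-math.sin(th), math.cos(th), 0.0])
        for t, (i, j) in enumerate(st):
            r = hub_radius + t * 1.0
            coords[i] = r * d + 0.5 * span * perp
            coords[j] = r * d - 0.5 * span * perp
        # hairpin loop between the innermost pair
        i_in, j_in = st[-1]
        loop_idx = [k for k in range(i_in + 1, j_in)]
        q = len(loop_idx)
        tip = (hub_radius + (len(st) - 1) * 1.0 + 0.5) * d
        for t, k in enumerate(loop_idx):
            phi = math.pi * (t + 1) / (q + 1)
            # sweep from +perp through +d to -perp
            coords[k] = tip + 0.5 * span * (math.cos(phi) * perp
                                            + math.sin(phi) * d)

    # linkers and dangling ends on hub arcs
    unplaced = [k for k in range(n) if np.isnan(coords[k, 0])]
    runs = []
    for k in unplaced:
        if runs and runs[-1][-1] == k - 1:
            runs[-1].append(k)
        else:
            runs.append([k])
    for run in runs:
        prev_pt = coords[run[0] - 1] if run[0] > 0 else None
        next_pt = coords[run[-1] + 1] if run[-1] + 1 < n else None
        if prev_pt is None and next_pt is None:
            a0, a1 = 0.0, math.pi
        elif prev_pt is None:
            a1 = math.atan2(next_pt[1], next_pt[0])
            a0 = a1 - 0.5
        elif next_pt is None:
            a0 = math.atan2(prev_pt[1], prev_pt[0])
            a1 = a0 + 0.5
        else:
            a0 = math.atan2(prev_pt[1], prev_pt[0])
            a1 = math.atan2(next_pt[1], next_pt[0])
            if a1 <= a0:
                a1 += 2.0 * math.pi
        r = hub_radius * 0.7
        q = len(run)
        for t, k in enumerate(run):
            ang = a0 + (a1 - a0) * (t + 1) / (q + 1)
            coords[k] = np.array([r * math.cos(ang), r * math.sin(ang), 0.0])
    return coords


# ---------------------------------------------------------------------------
# trans-membrane bundles

def build_tm_bundle(helices, container_radius_angstrom: float,
                    container_length_angstrom: float,
                    n_res: int | None = None) -> Node:
    """A bundle of trans-membrane helices inside a confining tube.

    ``helices`` are (start, end) residue ranges (end exclusive).  Each helix
    is built as an ideal alpha-helix in its own tube; the helix tubes are
    children of one large tube whose axis is the membrane normal.  Helix
    tube ends are free to protrude, so helices can tilt.
    """
    scale = constants.PROTEIN_UNITS_PER_ANGSTROM
    if n_res is None:
        n_res = max(e for _, e in helices)
    sse = ["C"] * n_res
    for s, e in helices:
        for k in range(s, e):
            sse[k] = "H"
    sse = "".join(sse)

    ca = np.zeros((n_res, 3))
    nh = len(helices)
    circle_r = max(container_radius_angstrom - constants.SSE_TUBE_RADIUS_ANGSTROM["H"] - 2.0,
                   container_radius_angstrom * 0.5)
    ends = []
    for k, (s, e) in enumerate(helices):
        th = 2.0 * math.pi * k / nh
        off = np.array([circle_r * math.cos(th), circle_r * math.sin(th), 0.0])
        h = ideal_helix(e - s)
        h = h - h.mean(axis=0)
        if k % 2 == 1:
            h = h[::-1] * np.array([1.0, -1.0, -1.0])   # antiparallel topology
        ca[s:e] = h + off
        ends.append((s, e))
    # crude linker placement between consecutive helix ends
    for (s0, e0), (s1, e1) in zip(ends, ends[1:]):
        a = ca[e0 - 1]
        b = ca[s1]
        for t, k in enumerate(range(e0, s1)):
            f = (t + 1) / (s1 - e0 + 1)
            ca[k] = a + f * (b - a)

    root = Node(Tube(np.array([0.0, 0.0, -0.5 * container_length_angstrom * scale]),
                     np.array([0.0, 0.0, +0.5 * container_length_angstrom * scale]),
                     container_radius_angstrom * scale),
                level=0, kind="membrane_tube")
    pts = ca * scale
    atom_r = 0.5 * constants.PROTEIN_BUMP_DIAMETER_ANGSTROM * scale
    residues = [Node(Sphere(p, atom_r), level=2, kind="protein_atom")
                for p in pts]
    for i, r in enumerate(residues):
        r.label = i
    for a, b in zip(residues, residues[1:]):
        a.bond_to(b, constants.PROTEIN_BOND_UNITS)
    preset_links(residues, sse)
    for k, (s, e) in enumerate(helices):
        run = pts[s:e]
        axis = _unit(run[-1] - run[0])
        centroid = run.mean(axis=0)
        length = (e - s) * constants.SSE_RISE_ANGSTROM["H"] * scale
        tube = Tube(centroid - 0.5 * length * axis,
                    centroid + 0.5 * length * axis,
                    constants.SSE_TUBE_RADIUS_ANGSTROM["H"] * scale)
        hn = Node(tube, level=1, kind="sse_alpha")
        for r in residues[s:e]:
            hn.add_child(r)
        root.add_child(hn)
    for k in range(n_res):
        if sse[k] == "C":
            residues[k].level = 1
            root.add_child(residues[k])
    return root


# ---------------------------------------------------------------------------
# PDB traces

def read_trace(pdb_text: str, atom_name: str = "CA") -> np.ndarray:
    """Ordered coordinates (Angstrom) of one named atom per residue from
    PDB-format text (all chains, first altloc)."""
    import gemmi
    if not pdb_text.strip():
        raise ValueError("empty PDB input")
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    out = []
    model = st[0]
    for chain in model:
        for res in chain:
            picked = None
            for atom in res:
                if atom.name == atom_name.strip():
                    picked = atom
                    break
            if picked is not None:
                out.append([picked.pos.x, picked.pos.y, picked.pos.z])
            elif any(a.name in ("CA", "P") for a in res) or len(res) > 1:
                warnings.warn(
                    f"residue {chain.name}/{res.seqid.num} lacks atom "
                    f"{atom_name}; skipped")
    if not out:
        raise ValueError(f"no {atom_name} atoms found")
    return np.array(out)


def write_trace(frames, atom_name: str = "CA") -> str:
    """Multi-model PDB text for a trajectory of coordinate frames
    (Angstrom).  One pseudo-residue per coordinate."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    res_name = "GLY" if atom_name.strip() == "CA" else "  U"
    lines = []
    for m, frame in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i, (x, y, z) in enumerate(frame, start=1):
            lines.append(
                f"ATOM  {i:5d} {atom_name:>3s}  {res_name:>3s} A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00")
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
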