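"""Parameter-file parsing (JSON dialect) and fixture generation.

A parameter file holds one record per hierarchy level with the step sizes
``hard``, ``soft``, ``keep``, ``bump`` and ``bond``, plus global settings
(seed, steps, slow factor, keeper margins).  Files round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .hierarchy import ParamRecord, ParamSet

__all__ = ["ParameterFile", "parse_params", "dump_params", "make_fixture"]

_LEVEL_KEYS = {"hard", "soft", "keep", "bump", "bond"}
_GLOBAL_KEYS = {"seed", "steps", "slow_factor", "margin_in", "margin_out",
                "levels"}


@dataclass
class ParameterFile:
    params: ParamSet
    seed: int = 0
    steps: int = 100

    def to_json(self) -> str:
        levels = {}
        for lv in sorted(self.params.levels):
            r = self.params.at(lv)
            rec = {}
            for k in ("hard", "soft", "keep", "bond"):
                v = getattr(r, k)
                if v is not None:
                    rec[k] = v
            if r.bump != 1.0:
                rec["bump"] = r.bump
            levels[str(lv)] = rec
        doc = {"levels": levels, "seed": self.seed, "steps": self.steps,
               "slow_factor": self.params.slow_factor,
               "margin_in": self.params.margin_in,
               "margin_out": self.params.margin_out}
        return json.dumps(doc, indent=2, sort_keys=True)


def parse_params(text: str) -> ParameterFile:
    """Parse a JSON parameter file, validating keys and value ranges."""
    doc = json.loads(text) if text.strip() else {}
    if not isinstance(doc, dict):
        raise ValueError("parameter file must be a JSON object")
    unknown = set(doc) - _GLOBAL_KEYS
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    levels = {}
    for lv_str, rec in doc.get("levels", {}).items():
        try:
            lv = int(lv_str)
        except ValueError:
            raise ValueError(f"level key {lv_str!r} is not an integer")
        unknown = set(rec) - _LEVEL_KEYS
        if unknown:
            raise ValueError(f"level {lv}: unknown keys {sorted(unknown)}")
        for k in ("hard", "soft", "bond"):
            if k in rec and rec[k] is not None and rec[k] < 0:
                raise ValueError(f"level {lv}: {k} must be >= 0")
        levels[lv] = ParamRecord(rec.get("hard"), rec.get("soft"),
                                 rec.get("keep"), rec.get("bump", 1.0),
                                 rec.get("bond"))
    ps = ParamSet(levels,
                  slow_factor=float(doc.get("slow_factor", 1.0)),
                  margin_in=float(doc.get("margin_in", 0.9)),
                  margin_out=float(doc.get("margin_out", 1.1)))
    if ps.slow_factor <= 0:
        raise ValueError("slow_factor must be > 0")
    return ParameterFile(ps, seed=int(doc.get("seed", 0)),
                         steps=int(doc.get("steps", 100)))


def dump_params(pf: ParameterFile) -> str:
    return pf.to_json()


def make_fixture(name: str, outdir) -> list[str]:
    """Write a self-contained input set (coordinates, hierarchy JSON and a
    parameter file) for one of the built-in test systems."""
    import json as _json
    from pathlib import Path

    import numpy as np

    from . import builders
    from .hierarchy import leaves

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _write(fname: str, text: str) -> None:
        p = outdir / fname
        p.write_text(text)
        written.append(str(p))

    if name.startswith("hilbert"):
        levels = int(name[len("hilbert"):])
        root = builders.hilbert_chain(levels)
        pts = np.array([n.center for n in leaves(root)])
        _write(f"{name}_coords.txt",
               "\n".join(f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in pts) + "\n")
        _write(f"{name}_hierarchy.json", _json.dumps(
            {"kind": "hilbert", "levels": levels, "bond": 1.0}, indent=2))
        pf = ParameterFile(ParamSet({lv: ParamRecord(hard=1.0, soft=0.1,
                                                     keep=0.1, bond=0.1)
                                     for lv in range(1, levels + 1)}))
        _write(f"{name}_params.json", pf.to_json())
    elif name == "toy_protein":
        sse = "CC" + "H" * 10 + "CCC" + "E" * 5 + "CC"
        ca = _toy_protein_trace(sse)
        _write("toy_protein_ca.txt",
               "\n".join(f"{x:.4f} {y:.4f} {z:.4f}" for x, y, z in ca) + "\n")
        _write("toy_protein_hierarchy.json", _json.dumps(
            {"kind": "protein", "sse": sse, "domains": [[0, len(sse)]]},
            indent=2))
        pf = ParameterFile(ParamSet({0: ParamRecord(keep=0.05),
                                     1: ParamRecord(hard=0.5, soft=0.2,
                                                    keep=0.05, bond=0.05),
                                     2: ParamRecord(hard=1.0, keep=None,
                                                    bond=0.05)}))
        _write("toy_protein_params.json", pf.to_json())
    elif name == "toy_rna":
        pairs = _toy_rna_pairs()
        n = 48
        coords = builders.layout_cloverleaf(pairs, n)
        _write("toy_rna_p.txt",
               "\n".join(f"{x:.4f} {y:.4f} {z:.4f}" for x, y, z in coords) + "\n")
        _write("toy_rna_pairs.txt",
               "\n".join(f"{i} {j}" for i, j in pairs) + "\n")
        pf = ParameterFile(ParamSet({0: ParamRecord(keep=0.1),
                                     1: ParamRecord(hard=0.2, soft=0.1,
                                                    keep=0.1, bond=0.05),
                                     2: ParamRecord(hard=0.5, keep=0.1,
                                                    bond=0.05),
                                     3: ParamRecord(hard=1.0, bond=0.05)}))
        _write("toy_rna_params.json", pf.to_json())
    elif name == "tm7":
        helices = [(3 + 26 * k, 3 + 26 * k + 22) for k in range(7)]
        _write("tm7_helices.txt",
               "\n".join(f"{s} {e}" for s, e in helices) + "\n")
        _write("tm7_hierarchy.json", _json.dumps(
            {"kind": "tm_bundle", "helices": helices,
             "container_radius_angstrom": 18.0,
             "container_length_angstrom": 45.0}, indent=2))
        pf = ParameterFile(ParamSet({0: ParamRecord(keep=-0.05),
                                     1: ParamRecord(hard=0.2, soft=0.1,
                                                    keep=0.05, bond=0.05),
                                     2: ParamRecord(hard=1.0, bond=0.05)}))
        _write("tm7_params.json", pf.to_json())
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return written


def _toy_protein_trace(sse: str):
    """A synthetic Ca trace following the secondary-structure string: ideal
    helix/strand geometry with simple linkers (synthetic stand-in, not a
    crystal structure)."""
    import numpy as np

    from .builders import ideal_helix

    pts = []
    cursor = np.zeros(3)
    direction = 1.0
    i = 0
    while i < len(sse):
        j = i
        while j < len(sse) and sse[j] == sse[i]:
            j += 1
        n = j - i
        if sse[i] == "H":
            seg = ideal_helix(n)
        elif sse[i] == "E":
            seg = np.column_stack([np.zeros(n), np.zeros(n),
                                   3.3 * np.arange(n)])
        else:
            seg = np.column_stack([1.5 * np.arange(n), np.zeros(n),
                                   2.0 * np.arange(n)])
        seg = seg - seg[0]
        seg = seg * np.array([1.0, 1.0, direction])
        pts.extend((cursor + s) for s in seg)
        cursor = pts[-1] + np.array([4.5, 1.0, 0.0])
        direction = -direction
        i = j
    return np.array(pts)


def _toy_rna_pairs():
    """Two 6-bp stems with 4-nt hairpin loops and short linkers (48 nt)."""
    pairs = []
    # stem 1: 2..7 paired with 21..16
    for t in range(6):
        pairs.append((2 + t, 21 - t))
    # stem 2: 26..31 paired with 45..40
    for t in range(6):
        pairs.append((26 + t, 45 - t))
    return pairs
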