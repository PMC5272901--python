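"""Unit conventions and ideal-geometry constants.

All simulation geometry lives in internal length units.  Proteins use the
convention that one virtual Ca-Ca bond (3.8 Angstrom) is 0.6 units; nucleic
acids use one P-P backbone bond as 1 unit.  Every conversion goes through
this module so builders and analysis round-trip exactly.

The duplex ideals (P-P span across a basepair, stacking rise, helical
twist) are editable defaults taken from canonical A-form (RNA) and B-form
(DNA) geometry expressed in the nucleic internal unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

# -- protein scale: 0.6 internal units per 3.8 A Ca-Ca bond ---------------
PROTEIN_BOND_ANGSTROM = 3.8
PROTEIN_BOND_UNITS = 0.6
PROTEIN_UNITS_PER_ANGSTROM = PROTEIN_BOND_UNITS / PROTEIN_BOND_ANGSTROM

# -- nucleic scale: 1 internal unit per P-P backbone bond -----------------
NUCLEIC_BOND_ANGSTROM = 5.9          # A-form backbone P-P distance
NUCLEIC_UNITS_PER_ANGSTROM = 1.0 / NUCLEIC_BOND_ANGSTROM


def protein_to_internal(x_angstrom):
    return x_angstrom * PROTEIN_UNITS_PER_ANGSTROM


def internal_to_protein(x_units):
    return x_units / PROTEIN_UNITS_PER_ANGSTROM


# -- protein atomic bump convention ---------------------------------------
#: Minimal allowed i,i+2 Ca separation (Angstrom); the atomic bump diameter.
PROTEIN_BUMP_DIAMETER_ANGSTROM = 5.0

# -- secondary-structure tube presets (Angstrom) --------------------------
#: Axial displacement per residue by secondary structure.
SSE_RISE_ANGSTROM = {"H": 1.5, "E": 3.0, "C": 0.5}
#: Preset tube radii; the beta value is slightly generous to give the
#: strand room for super-helical twist on the surface.
SSE_TUBE_RADIUS_ANGSTROM = {"H": 2.3, "E": 2.7, "C": 2.0}

# -- hydrogen-bond-like preset link targets (Angstrom, Ca-Ca) -------------
HELIX_I_I3_ANGSTROM = 5.1
HELIX_I_I4_ANGSTROM = 6.2
STRAND_I_I2_ANGSTROM = 6.7


@dataclass(frozen=True)
class DuplexIdeal:
    """Ideal duplex geometry in nucleic internal units (1 = P-P bond)."""
    pp_span: float       # P-P distance across a basepair
    rise: float          # stacking separation between basepair centres
    twist: float         # helical twist per basepair, radians, right-handed


RNA_DUPLEX = DuplexIdeal(pp_span=3.0, rise=0.47, twist=math.radians(32.7))
DNA_DUPLEX = DuplexIdeal(pp_span=2.7, rise=0.48, twist=math.radians(36.0))

#: Radius of the small tube enclosing one basepair.
BASEPAIR_TUBE_RADIUS = 0.35
#: Atomic bump radius of a phosphate (bump diameter = 1 bond keeps the
#: backbone at steric equilibrium).
PHOSPHATE_BUMP_RADIUS = 0.5
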