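"""Static residue-level chemistry tables.

Covers the 20 standard amino acids with PDB v3 atom nomenclature,
including hydrogens.  The charge/LJ/GB numbers here form the shipped
illustrative parameter set; see :mod:`iem.forcefield` for the loader that
accepts user-supplied tables in the same schema.
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_AMINO_ACIDS = frozenset(THREE_TO_ONE)

# Backbone atom names; hydrogens bonded to N/CA are included so that the
# backbone/sidechain split partitions every standard residue.
BACKBONE_ATOM_NAMES = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3"}
)

# Atom classes: (lj_sigma [A], lj_epsilon [kcal/mol], gb_rho [A], gb_scale).
# LJ values follow common all-atom protein force-field magnitudes; GB radii
# follow the mbondi2 convention (H on N gets 1.3 A) with HCT screening
# factors per element.
ATOM_CLASSES = {
    "C":  (3.40, 0.0860, 1.70, 0.72),
    "N":  (3.25, 0.1700, 1.55, 0.79),
    "O":  (2.96, 0.2100, 1.50, 0.85),
    "S":  (3.56, 0.2500, 1.80, 0.96),
    "HC": (2.65, 0.0157, 1.20, 0.85),   # H on carbon
    "HN": (1.07, 0.0157, 1.30, 0.85),   # H on nitrogen
    "HX": (1.07, 0.0157, 1.20, 0.85),   # H on oxygen/sulfur
}

# Shared backbone template: (atom, class, charge).  Sums to zero.
_BB = [
    ("N", "N", -0.40), ("H", "HN", 0.25),
    ("CA", "C", 0.05), ("HA", "HC", 0.05),
    ("C", "C", 0.50), ("O", "O", -0.45),
]

# Side chains (and full overrides for GLY/PRO, whose backbones differ).
# Every neutral residue sums to 0 e; ASP/GLU to -1 e; LYS/ARG to +1 e.
# HIS is the neutral N-epsilon-H tautomer.
_SIDECHAINS: dict[str, list[tuple[str, str, float]]] = {
    "ALA": [("CB", "C", -0.15), ("HB1", "HC", 0.05), ("HB2", "HC", 0.05),
            ("HB3", "HC", 0.05)],
    "ARG": [("CB", "C", -0.10), ("HB2", "HC", 0.05), ("HB3", "HC", 0.05),
            ("CG", "C", -0.10), ("HG2", "HC", 0.05), ("HG3", "HC", 0.05),
            ("CD", "C", 0.10), ("HD2", "HC", 0.05), ("HD3", "HC", 0.05),
            ("NE", "N", -0.50), ("HE", "HN", 0.30), ("CZ", "C", 0.80),
            ("NH1", "N", -0.60), ("HH11", "HN", 0.35), ("HH12", "HN", 0.35),
            ("NH2", "N", -0.60), ("HH21", "HN", 0.35), ("HH22", "HN", 0.35)],
    "ASN": [("CB", "C", -0.10), ("HB2", "HC", 0.05), ("HB3", "HC", 0.05),
            ("CG", "C", 0.55), ("OD1", "O", -0.55),
            ("ND2", "N", -0.60), ("HD21", "HN", 0.30), ("HD22", "HN", 0.30)],
    "ASP": [("CB", "C", -0.10), ("HB2", "HC", 0.05), ("HB3", "HC", 0.05),
            ("CG", "C", 0.60), ("OD1", "O", -0.80), ("OD2", "O", -0.80)],
    "CYS": [("CB", "C", -0.10), ("HB2", "HC", 0.05), ("HB3", "HC", 0.05),
            ("SG", "S", -0.20), ("HG", "HX", 0.20)],
    "GLN": [("CB", "C", -0.10), ("HB2", "HC", 0.05), ("HB3", "HC", 0.05),
            ("CG", "C", -0.10), ("HG2", "HC", 0.05), ("HG3", "HC", 0.05),
            ("CD", "C", 0.55), ("OE1", "O", -0.55),
            ("NE2", "N", -0.60), ("HE21", "HN", 0.30), ("HE22", "HN", 0.30)],
    "GLU": [("CB", "C", -0.10), ("HB2", "HC", 0.05), ("HB3", "HC", 0.05),
            ("CG", "C", -0.10), ("HG2", "HC", 0.05), ("HG3", "HC", 0.05),
            ("CD", "C", 0.60), ("OE1", "O", -0.80), ("OE2", "O", -0.80)],
    "HIS": [("CB", "C", -0.10), ("HB2", "HC", 0.05), ("HB3", "HC", 0.05),
            ("CG", "C", 0.10), ("ND1", "N", -0.50),
            ("CE1", "C", 0.30), ("HE1", "HC", 0.10),
            ("NE2", "N", -0.50), ("HE2", "HN", 0.35),
            ("CD2", "C", 0.05), ("HD2", "HC", 0.10)],
    "ILE": [("CB", "C", -0.05), ("HB", "HC", 0.05),
            ("CG1", "C", -0.10), ("HG12", "HC", 0.05), ("HG13", "HC", 0.05),
            ("CG2", "C", -0.15), ("HG21", "HC", 0.05), ("HG22", "HC", 0.05),
            ("HG23", "HC", 0.05),
            ("CD1", "C", -0.15), ("HD11", "HC", 0.05), ("HD12", "HC", 0.05),
            ("HD13", "HC", 0.05)],
    "LEU": [("CB", "C", -0.10), ("HB2", "HC", 0.05), ("HB3", "HC", 0.05),
            ("CG", "C", -0.05), ("HG", "HC", 0.05),
            ("CD1", "C", -0.15), ("HD11", "HC", 0.05), ("HD12", "HC", 0.05),
            ("HD13", "HC", 0.05),
            ("CD2", "C", -0.15), ("HD21", "HC", 0.05), ("HD22", "HC", 0.05),
            ("HD23", "HC", 0.05)],
    "LYS": [("CB", "C", -0.10), ("HB2", "HC", 0.05), ("HB3", "HC", 0.05),
            ("CG", "C", -0.10), ("HG2", "HC", 0.05), ("HG3", "HC", 0.05),
            ("CD", "C", -0.10), ("HD2", "HC", 0.05), ("HD3", "HC", 0.05),
            ("CE", "C", 0.10), ("HE2", "HC", 0.05), ("HE3", "HC", 0.05),
            ("NZ", "N", -0.40), ("HZ1", "HN", 0.40), ("HZ2", "HN", 0.40),
            ("HZ3", "HN", 0.40)],
    "MET": [("CB", "C", -0.10), ("HB2", "HC", 0.05), ("HB3", "HC", 0.05),
            ("CG", "C", -0.05), ("HG2", "HC", 0.05), ("HG3", "HC", 0.05),
            ("SD", "S", -0.20),
            ("CE", "C", 0.00), ("HE1", "HC", 0.05), ("HE2", "HC", 0.05),
            ("HE3", "HC", 0.05)],
    "PHE": [("CB", "C", -0.10), ("HB2", "HC", 0.05), ("HB3", "HC", 0.05),
            ("CG", "C", 0.00),
            ("CD1", "C", -0.10), ("HD1", "HC", 0.10),
            ("CD2", "C", -0.10), ("HD2", "HC", 0.10),
            ("CE1", "C", -0.10), ("HE1", "HC", 0.10),
            ("CE2", "C", -0.10), ("HE2", "HC", 0.10),
            ("CZ", "C", -0.10), ("HZ", "HC", 0.10)],
    "SER": [("CB", "C", 0.05), ("HB2", "HC", 0.05), ("HB3", "HC", 0.05),
            ("OG", "O", -0.55), ("HG", "HX", 0.40)],
    "THR": [("CB", "C", 0.10), ("HB", "HC", 0.05),
            ("OG1", "O", -0.55), ("HG1", "HX", 0.40),
            ("CG2", "C", -0.15), ("HG21", "HC", 0.05), ("HG22", "HC", 0.05),
            ("HG23", "HC", 0.05)],
    "TRP": [("CB", "C", -0.10), ("HB2", "HC", 0.05), ("HB3", "HC", 0.05),
            ("CG", "C", 0.00),
            ("CD1", "C", -0.05), ("HD1", "HC", 0.10),
            ("NE1", "N", -0.55), ("HE1", "HN", 0.35),
            ("CE2", "C", 0.15), ("CD2", "C", 0.00),
            ("CE3", "C", -0.10), ("HE3", "HC", 0.10),
            ("CZ3", "C", -0.10), ("HZ3", "HC", 0.10),
            ("CZ2", "C", -0.10), ("HZ2", "HC", 0.10),
            ("CH2", "C", -0.10), ("HH2", "HC", 0.10)],
    "TYR": [("CB", "C", -0.10), ("HB2", "HC", 0.05), ("HB3", "HC", 0.05),
            ("CG", "C", 0.00),
            ("CD1", "C", -0.10), ("HD1", "HC", 0.10),
            ("CD2", "C", -0.10), ("HD2", "HC", 0.10),
            ("CE1", "C", -0.10), ("HE1", "HC", 0.10),
            ("CE2", "C", -0.10), ("HE2", "HC", 0.10),
            ("CZ", "C", 0.15), ("OH", "O", -0.55), ("HH", "HX", 0.40)],
    "VAL": [("CB", "C", -0.05), ("HB", "HC", 0.05),
            ("CG1", "C", -0.15), ("HG11", "HC", 0.05), ("HG12", "HC", 0.05),
            ("HG13", "HC", 0.05),
            ("CG2", "C", -0.15), ("HG21", "HC", 0.05), ("HG22", "HC", 0.05),
            ("HG23", "HC", 0.05)],
}

# GLY: no CB, two HA; CA charge dropped to keep the residue neutral.
_GLY = [
    ("N", "N", -0.40), ("H", "HN", 0.25),
    ("CA", "C", 0.00), ("HA2", "HC", 0.05), ("HA3", "HC", 0.05),
    ("C", "C", 0.50), ("O", "O", -0.45),
]
# PRO: no amide H; ring CD bound to N.  Backbone deficit balanced in ring.
_PRO = [
    ("N", "N", -0.25),
    ("CA", "C", 0.05), ("HA", "HC", 0.05),
    ("C", "C", 0.50), ("O", "O", -0.45),
    ("CB", "C", -0.10), ("HB2", "HC", 0.05), ("HB3", "HC", 0.05),
    ("CG", "C", -0.10), ("HG2", "HC", 0.05), ("HG3", "HC", 0.05),
    ("CD", "C", 0.00), ("HD2", "HC", 0.05), ("HD3", "HC", 0.05),
]


def residue_template_rows(resname: str) -> list[tuple[str, str, float]]:
    """Full (atom, class, charge) rows for one standard residue."""
    if resname == "GLY":
        return list(_GLY)
    if resname == "PRO":
        return list(_PRO)
    return list(_BB) + _SIDECHAINS[resname]


# Name-based terminal patches (applied when the marker atoms are present).
# N-terminus: protonated amine, +1 e; C-terminus: carboxylate, -1 e.
NTERM_PATCH = {
    "H1": ("HN", 0.30), "H2": ("HN", 0.30), "H3": ("HN", 0.30),
    "N": ("N", -0.30),
}
CTERM_PATCH = {
    "OXT": ("O", -0.75), "O": ("O", -0.75), "C": ("C", 0.55),
}

# Graph distance (bond count) from any backbone atom to the carbonyl C of
# its own residue, and from the amide N to atoms of its own residue.  Only
# separations <= 2 matter: across the peptide bond they yield total
# separations of 1-2, 1-3 or 1-4 used by the force-field exclusion policy.
BOND_DIST_TO_C = {"C": 0, "CA": 1, "O": 1, "OXT": 1,
                  "N": 2, "HA": 2, "HA2": 2, "HA3": 2, "CB": 2}
BOND_DIST_FROM_N = {"N": 0, "CA": 1, "H": 1, "H1": 1, "H2": 1, "H3": 1,
                    "CD": 1,   # proline ring closure
                    "C": 2, "CB": 2, "HA": 2, "HA2": 2, "HA3": 2}
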