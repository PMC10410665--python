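"""Packaged lookup tables: species roles, element properties, residue chemistry.

All tables are plain dicts so callers can copy and override them; none of the
analysis functions mutate them.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23  # 1/mol

#: Default molar masses, g/mol.  TBA is tert-butyl alcohol.
MOLAR_MASS = {
    "water": 18.015,
    "tba": 74.12,
    "mannitol": 182.17,
    "sucrose": 342.30,
}

#: Residue-name -> species role.  Anything not listed maps to "excipient".
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation-variant names
    "HID", "HIE", "HIP", "HSD", "HSE", "HSP", "CYX", "ASH", "GLH", "LYN",
}

DEFAULT_SPECIES_MAP = {
    **{aa: "protein" for aa in AMINO_ACIDS},
    "SOL": "water", "HOH": "water", "WAT": "water", "TIP3": "water",
    "SPC": "water", "TIP": "water",
    "TBA": "tba", "TBU": "tba",
    "CL": "ion", "CL-": "ion", "NA": "ion", "NA+": "ion", "K": "ion",
    "K+": "ion", "CA": "ion", "MG": "ion", "ZN": "ion",
}


def species_from_residue(residue_name: str, species_map=None) -> str:
    """Map a residue name to its role tag (protein/water/tba/ion/excipient)."""
    table = DEFAULT_SPECIES_MAP if species_map is None else species_map
    return table.get(residue_name.strip().upper(), "excipient")


#: Atomic masses (amu) by element symbol.
ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "CL": 35.45, "NA": 22.990, "K": 39.098, "CA": 40.078,
    "MG": 24.305, "FE": 55.845, "ZN": 65.38, "AR": 39.948,
}

#: Bondi-style van der Waals radii, nm.
ELEMENT_VDW_RADIUS = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180,
    "P": 0.180, "CL": 0.175, "NA": 0.227, "K": 0.275, "CA": 0.231,
    "MG": 0.173, "FE": 0.200, "ZN": 0.139, "AR": 0.188,
}

_TWO_LETTER = {"CL", "NA", "CA", "MG", "FE", "ZN", "AR"}


def guess_element(atom_name: str, residue_name: str | None = None) -> str:
    """Infer the element symbol from an atom name (GRO/PDB style).

    Leading digits are skipped ("1HB" -> H).  Two-letter elements are
    recognised by prefix, except inside amino-acid residues where names
    like CA/CB are carbons and CL would shadow a chlorine-free backbone:
    there the single-letter rule always applies.
    """
    s = atom_name.strip().upper().lstrip("0123456789")
    if not s:
        return ""
    in_protein = (residue_name is not None
                  and residue_name.strip().upper() in AMINO_ACIDS)
    if not in_protein and s[:2] in _TWO_LETTER:
        return s[:2]
    return s[0]


def element_mass(atom_name: str, residue_name: str | None = None,
                 default: float = 12.011) -> float:
    return ELEMENT_MASS.get(guess_element(atom_name, residue_name), default)


def element_vdw_radius(atom_name: str, residue_name: str | None = None,
                       default: float = 0.170) -> float:
    return ELEMENT_VDW_RADIUS.get(guess_element(atom_name, residue_name),
                                  default)


#: Residue chemistry classes used for contact-occupancy aggregation.
RESIDUE_CLASS = {
    **{r: "positive" for r in ("LYS", "ARG", "HIS", "HID", "HIE", "HIP",
                               "HSD", "HSE", "HSP")},
    **{r: "negative" for r in ("ASP", "GLU")},
    **{r: "polar" for r in ("SER", "THR", "ASN", "GLN", "TYR", "CYS")},
    **{r: "apolar" for r in ("ALA", "VAL", "LEU", "ILE", "PRO", "PHE",
                             "MET", "TRP", "GLY")},
}
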