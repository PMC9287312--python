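"""Bundled per-atom parameter tables for fixtures and toy systems.

Charges are a simplified point-charge model (not a force field): each
residue/nucleotide carries a small set of chemically sensible partial
charges which are renormalised per residue to an integer net charge
(phosphate-bearing nucleotides -1 e, Arg/Lys +1 e, Asp/Glu -1 e,
everything else 0). Lennard-Jones well depths / rmin-half values and
solvation radii are per-element, in the range of common biomolecular
force fields. Atom typing proper is out of scope: real systems take
charges and radii from a PQR file.
"""

from __future__ import annotations

# --- per-element parameters -------------------------------------------------

# kcal/mol, Angstrom (rmin/2)
ELEMENT_LJ: dict[str, tuple[float, float]] = {
    "H": (0.0157, 0.6000),
    "C": (0.0860, 1.9080),
    "N": (0.1700, 1.8240),
    "O": (0.2100, 1.6612),
    "P": (0.2000, 2.1000),
    "S": (0.2500, 2.0000),
}

# solvation / surface radii (mbondi-like), Angstrom
ELEMENT_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.50,
    "P": 1.85,
    "S": 1.80,
}

ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

# used only for bond inference (donor typing in fingerprints)
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "P": 1.07,
    "S": 1.05,
}

# --- simplified partial charges ---------------------------------------------

# raw (pre-normalisation) charges by atom name, shared protein backbone
_BACKBONE = {"N": -0.42, "H": 0.27, "CA": 0.03, "C": 0.60, "O": -0.57}

# side-chain raw charges per residue type
_SIDECHAINS: dict[str, dict[str, float]] = {
    "GLY": {},
    "ALA": {"CB": -0.06},
    "PHE": {"CB": -0.10, "CG": 0.01, "CD1": -0.08, "CD2": -0.08,
            "CE1": -0.08, "CE2": -0.08, "CZ": -0.08},
    "SER": {"CB": 0.05, "OG": -0.65, "HG": 0.43},
    "ASP": {"CB": -0.10, "CG": 0.75, "OD1": -0.80, "OD2": -0.80},
    "GLU": {"CB": -0.05, "CG": -0.05, "CD": 0.75, "OE1": -0.80, "OE2": -0.80},
    "LYS": {"CB": -0.05, "CE": 0.20, "NZ": -0.30, "HZ1": 0.33, "HZ2": 0.33,
            "HZ3": 0.33},
    "ARG": {"CB": -0.05, "NE": -0.55, "HE": 0.35, "CZ": 0.80,
            "NH1": -0.80, "NH2": -0.80, "HH11": 0.45, "HH12": 0.45,
            "HH21": 0.45, "HH22": 0.45},
    "TRP": {"CB": -0.10, "CG": -0.10, "CD1": -0.15, "NE1": -0.35, "HE1": 0.35,
            "CD2": 0.10, "CE2": 0.15, "CE3": -0.20, "CZ2": -0.25,
            "CZ3": -0.20, "CH2": -0.25},
}

PROTEIN_NET_CHARGE: dict[str, float] = {
    "LYS": 1.0, "ARG": 1.0, "ASP": -1.0, "GLU": -1.0,
}

# nucleotide raw charges: sugar-phosphate (reduced representation) + base
_SUGAR_PHOSPHATE = {
    "P": 1.17, "OP1": -0.78, "OP2": -0.78, "O5'": -0.50, "C5'": 0.06,
    "C4'": 0.11, "C3'": 0.20, "O3'": -0.52, "C1'": 0.07,
    # 5'-terminal cap (replaces the phosphate on nt1)
    "O5T": -0.62, "H5T": 0.42,
}

_BASES: dict[str, dict[str, float]] = {
    "A": {"N9": -0.03, "C8": 0.16, "N7": -0.57, "C5": 0.07, "C6": 0.70,
          "N6": -0.90, "H61": 0.41, "H62": 0.41, "N1": -0.76, "C2": 0.57,
          "N3": -0.69, "C4": 0.37},
    "G": {"N9": 0.05, "C8": 0.14, "N7": -0.57, "C5": 0.17, "C6": 0.48,
          "O6": -0.57, "N1": -0.48, "H1": 0.34, "C2": 0.76, "N2": -0.92,
          "H21": 0.42, "H22": 0.42, "N3": -0.66, "C4": 0.12},
    "U": {"N1": 0.04, "C2": 0.47, "O2": -0.55, "N3": -0.35, "H3": 0.32,
          "C4": 0.59, "O4": -0.57, "C5": -0.36, "C6": -0.11},
    "C": {"N1": -0.05, "C2": 0.75, "O2": -0.63, "N3": -0.77, "C4": 0.82,
          "N4": -0.95, "H41": 0.43, "H42": 0.43, "C5": -0.52, "C6": 0.01},
}


def residue_charge_table(resname: str) -> dict[str, float]:
    """Raw (un-normalised) charges for a protein residue or nucleotide."""
    if resname in _SIDECHAINS:
        table = dict(_BACKBONE)
        table.update(_SIDECHAINS[resname])
        return table
    if resname in _BASES:
        table = dict(_SUGAR_PHOSPHATE)
        table.update(_BASES[resname])
        return table
    raise KeyError(f"no bundled charges for residue type {resname!r}")


def residue_net_charge(resname: str, has_phosphate: bool = True) -> float:
    """Target integer net charge used for per-residue renormalisation."""
    if resname in _SIDECHAINS:
        return PROTEIN_NET_CHARGE.get(resname, 0.0)
    if resname in _BASES:
        return -1.0 if has_phosphate else 0.0
    raise KeyError(resname)


def element_of(atom_name: str) -> str:
    """Element symbol from a (toy/PDB-convention) atom name."""
    name = atom_name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")
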