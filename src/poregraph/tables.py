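"""Reference tables: residue classification, donor/acceptor roles, vdW radii.

All tables are plain dicts/sets so callers can copy and extend them; the
functions that consume them accept user overrides.
"""

from __future__ import annotations

# --- amino acids ------------------------------------------------------------

STANDARD_AA: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# modified residues treated as protein for census/sequence purposes;
# LYR is the retinylidene-lysine (lysine + covalently bound retinal)
PROTEIN_LIKE: dict[str, str] = {"MSE": "M", "LYR": "K"}

WATER_CODES = {"HOH", "WAT", "DOD", "H2O"}

MONATOMIC_ION_CODES = {
    "NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "NI", "CU", "CO",
    "CD", "HG", "BR", "IOD", "F", "LI", "RB", "CS",
}

# PEE is the PDB chemical component for dioleoylphosphatidylethanolamine (DOPE)
PHOSPHOLIPID_CODES = {"PEE", "PEF", "3PE", "6PE", "PE8", "POV", "PGV", "PC1", "LPP"}

STEROL_CODES = {"CLR", "CHS", "Y01", "ERG"}

RETINAL_CODES = {"RET", "LYR"}


# --- hydrogen-bond donor/acceptor roles -------------------------------------
# Side-chain polar heteroatoms only; backbone N/O deliberately excluded
# because the graphs describe side-chain/water networks. Hydroxyls and
# water oxygens can both donate and accept; His ring nitrogens are kept
# ambivalent because protonation states are unknown in an X-ray/cryo-EM
# model without hydrogens. Met SD is a weak acceptor; Cys SG a weak
# donor/acceptor. LYS NZ doubles as the retinal Schiff-base nitrogen when
# lysine carries the chromophore (component LYR).

DONOR = "donor"
ACCEPTOR = "acceptor"
BOTH = "both"

DEFAULT_DONOR_ACCEPTOR: dict[tuple[str, str], str] = {
    ("SER", "OG"): BOTH,
    ("THR", "OG1"): BOTH,
    ("TYR", "OH"): BOTH,
    ("ASN", "OD1"): ACCEPTOR,
    ("ASN", "ND2"): DONOR,
    ("GLN", "OE1"): ACCEPTOR,
    ("GLN", "NE2"): DONOR,
    ("ASP", "OD1"): ACCEPTOR,
    ("ASP", "OD2"): ACCEPTOR,
    ("GLU", "OE1"): ACCEPTOR,
    ("GLU", "OE2"): ACCEPTOR,
    ("LYS", "NZ"): DONOR,
    ("LYR", "NZ"): DONOR,  # retinal Schiff-base nitrogen
    ("ARG", "NE"): DONOR,
    ("ARG", "NH1"): DONOR,
    ("ARG", "NH2"): DONOR,
    ("HIS", "ND1"): BOTH,
    ("HIS", "NE2"): BOTH,
    ("TRP", "NE1"): DONOR,
    ("CYS", "SG"): BOTH,
    ("MET", "SD"): ACCEPTOR,
    ("HOH", "O"): BOTH,
    ("WAT", "O"): BOTH,
    ("DOD", "O"): BOTH,
}


# --- van der Waals radii (Bondi 1964, Å) ------------------------------------

VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39,
    "FE": 2.00, "MN": 2.00, "CU": 1.40, "SE": 1.90,
}

DEFAULT_VDW = 1.70  # fallback for elements not in the table


def vdw_radius(element: str) -> float:
    """vdW radius for an element symbol (case-insensitive)."""
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)
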