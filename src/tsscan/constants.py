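"""Physical constants, residue chemistry tables, and fixed parameter defaults.

Units throughout the package: distances in Å, charges in elementary charge
units (e), energies in kcal·mol⁻¹, temperatures in K, rates in s⁻¹.
"""

from __future__ import annotations

# Coulomb constant for point charges: kcal·Å·mol⁻¹·e⁻²
COULOMB_CONSTANT = 332.0637

# Gas constant, kcal·mol⁻¹·K⁻¹
GAS_CONSTANT = 1.98720e-3

# Boltzmann/Planck prefactor k_B/h, s⁻¹·K⁻¹ (Eyring prefactor per kelvin)
KB_OVER_H = 2.08366e10

# Default temperature for rate <-> activation free-energy conversion (K).
DEFAULT_TEMPERATURE = 310.0

# Default shell cutoff around the active site (Å).
DEFAULT_SHELL_CUTOFF = 10.0

# Default label threshold for scan plots (kcal·mol⁻¹).
DEFAULT_LABEL_THRESHOLD = 1.0

# Minimum allowed charge-charge distance before the Coulomb sum refuses (Å).
DEFAULT_MIN_DISTANCE_GUARD = 0.05

# Standard atomic weights (u) for the elements that occur in protein heavy
# atoms plus hydrogen; used for center-of-mass reference points.
ATOMIC_WEIGHTS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

# The 20 standard amino acids (3-letter codes).
STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Protonation/tautomer variants mapped back to their parent residue.
AA3_VARIANTS = {
    "HID": "HIS", "HIE": "HIS", "HIP": "HIS", "HSD": "HIS", "HSE": "HIS",
    "HSP": "HIS", "CYX": "CYS", "CYM": "CYS", "ASH": "ASP", "GLH": "GLU",
    "LYN": "LYS", "ARN": "ARG", "TYM": "TYR",
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# Water and common monatomic-ion residue names: present for energetics, never
# mutable, never part of the shell.
WATER_NAMES = {"HOH", "WAT", "TIP", "TIP3", "SPC", "SOL"}
ION_NAMES = {"NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "CU", "BR", "IOD"}

# Residues never scanned: no side chain beyond Cβ to truncate (Gly, Ala) or a
# backbone-constrained ring (Pro).
SHELL_EXCLUDED_NAMES = {"GLY", "ALA", "PRO"}

# Backbone atom names (heavy + amide/alpha hydrogens).  Everything else in a
# residue is side chain; Cβ and its hydrogens are the part alanine keeps.
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HN",
                  "HA", "HA2", "HA3"}

# Heavy atoms of the charged group, used as the distance reference for charged
# residues: carboxyl for Asp/Glu, terminal amine for Lys, guanidinium for Arg.
CHARGED_GROUP_ATOMS = {
    "ASP": ("CG", "OD1", "OD2"),
    "GLU": ("CD", "OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("CZ", "NH1", "NH2", "NE"),
}

# Chemical classes used for coloring/interpretation of scan results.
CLASS_POSITIVE = "POSITIVE"
CLASS_NEGATIVE = "NEGATIVE"
CLASS_POLAR = "POLAR"
CLASS_APOLAR = "APOLAR"

RESIDUE_CLASS = {
    "ASP": CLASS_NEGATIVE, "GLU": CLASS_NEGATIVE,
    "LYS": CLASS_POSITIVE, "ARG": CLASS_POSITIVE,
    "SER": CLASS_POLAR, "THR": CLASS_POLAR, "ASN": CLASS_POLAR,
    "GLN": CLASS_POLAR, "TYR": CLASS_POLAR, "CYS": CLASS_POLAR,
    "HIS": CLASS_POLAR, "TRP": CLASS_POLAR,
    "VAL": CLASS_APOLAR, "LEU": CLASS_APOLAR, "ILE": CLASS_APOLAR,
    "MET": CLASS_APOLAR, "PHE": CLASS_APOLAR,
    # no side chain / backbone-constrained; not scanned but classifiable
    "GLY": CLASS_APOLAR, "ALA": CLASS_APOLAR, "PRO": CLASS_APOLAR,
}

CLASS_COLORS = {
    CLASS_POSITIVE: "tab:blue",
    CLASS_NEGATIVE: "tab:red",
    CLASS_POLAR: "tab:green",
    CLASS_APOLAR: "tab:gray",
}

# Alanine point-charge library (Amber-style backbone + methyl charges, e).
# Used by the ALA_LIBRARY truncation mode for the retained atoms.
ALANINE_LIBRARY_CHARGES = {
    "N": -0.4157, "H": 0.2719, "CA": 0.0337, "HA": 0.0823,
    "CB": -0.1825, "HB1": 0.0603, "HB2": 0.0603, "HB3": 0.0603,
    "C": 0.5973, "O": -0.5679,
}

# BLOSUM62 marginal amino-acid background frequencies (the p_i of the
# matrix's underlying target distribution), indexed by 1-letter code.
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}
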