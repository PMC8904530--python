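"""Physicochemical constant tables used by the sequence descriptors.

All residue keys use one-letter codes. Values are widely published scales;
each table notes its provenance in the name or comment so a user can swap in
alternatives (the AAI descriptor accepts any index set of the same shape).
"""

from __future__ import annotations

#: Synonymous-codon counts of the standard genetic code (61 sense codons),
#: used by the dipeptide-deviation-from-expected-mean descriptor.
CODON_COUNTS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3, "K": 2,
    "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6, "T": 4, "V": 4,
    "W": 1, "Y": 2,
}

# --- Composition/Transition/Distribution groupings -------------------------
# 13 properties x 3 groups: seven hydrophobicity scales plus van der Waals
# volume, polarity, polarizability, charge, secondary structure and solvent
# accessibility. Group strings partition the 20 standard residues.
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MPSTHY"),
}

# --- Pseudo-amino-acid-composition property scales --------------------------
# Hydrophobicity (Tanford-style consensus scale used by classic PseAAC),
# Hopp-Woods hydrophilicity, and side-chain mass. Each is standardized to
# zero mean / unit variance over the 20 residues before use.
PAAC_HYDROPHOBICITY = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}
PAAC_HYDROPHILICITY = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2, "E": 3.0,
    "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3,
    "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3,
    "V": -1.5,
}
PAAC_SIDECHAIN_MASS = {
    "A": 15.0, "R": 101.0, "N": 58.0, "D": 59.0, "C": 47.0, "Q": 72.0,
    "E": 73.0, "G": 1.0, "H": 82.0, "I": 57.0, "L": 57.0, "K": 73.0,
    "M": 75.0, "F": 91.0, "P": 42.0, "S": 31.0, "T": 45.0, "W": 130.0,
    "Y": 107.0, "V": 43.0,
}

# --- Default 11-index set for the AAindex-style descriptor ------------------
# Hydropathy (Kyte-Doolittle), hydrophilicity (Hopp-Woods), residue mass,
# residue volume (Chothia), polarity (Grantham), isoelectric point
# (Zimmerman), average flexibility (Bhaskaran-Ponnuswamy), accessible
# surface area (Janin), and the three Chou-Fasman conformational
# propensities. User-overridable in encode_aai.
DEFAULT_AAINDEX: dict[str, dict[str, float]] = {
    "hydropathy_KYTJ820101": {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
        "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
        "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
        "Y": -1.3, "V": 4.2,
    },
    "hydrophilicity_HOPT810101": dict(PAAC_HYDROPHILICITY),
    "residue_mass": {
        "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
        "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
        "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
        "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
    },
    "residue_volume_CHOC750101": {
        "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
        "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
        "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
        "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
    },
    "polarity_GRAR740102": {
        "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
        "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
        "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
        "Y": 6.2, "V": 5.9,
    },
    "isoelectric_point_ZIMJ680104": {
        "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.05, "Q": 5.65,
        "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
        "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.66, "W": 5.89,
        "Y": 5.66, "V": 5.96,
    },
    "flexibility_BHAR880101": {
        "A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346,
        "Q": 0.493, "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462,
        "L": 0.365, "K": 0.466, "M": 0.295, "F": 0.314, "P": 0.509,
        "S": 0.507, "T": 0.444, "W": 0.305, "Y": 0.420, "V": 0.386,
    },
    "accessibility_JANJ780101": {
        "A": 27.8, "R": 94.7, "N": 60.1, "D": 60.6, "C": 15.5, "Q": 68.7,
        "E": 68.2, "G": 24.5, "H": 50.7, "I": 22.8, "L": 27.6, "K": 103.0,
        "M": 33.5, "F": 25.5, "P": 51.5, "S": 42.0, "T": 45.0, "W": 34.7,
        "Y": 55.2, "V": 23.7,
    },
    "alpha_helix_CHOP780201": {
        "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70, "Q": 1.11,
        "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08, "L": 1.21, "K": 1.16,
        "M": 1.45, "F": 1.13, "P": 0.57, "S": 0.77, "T": 0.83, "W": 1.08,
        "Y": 0.69, "V": 1.06,
    },
    "beta_sheet_CHOP780202": {
        "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19, "Q": 1.10,
        "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60, "L": 1.30, "K": 0.74,
        "M": 1.05, "F": 1.38, "P": 0.55, "S": 0.75, "T": 1.19, "W": 1.37,
        "Y": 1.47, "V": 1.70,
    },
    "beta_turn_CHOP780203": {
        "A": 0.66, "R": 0.95, "N": 1.56, "D": 1.46, "C": 1.19, "Q": 0.98,
        "E": 0.74, "G": 1.56, "H": 0.95, "I": 0.47, "L": 0.59, "K": 1.01,
        "M": 0.60, "F": 0.60, "P": 1.52, "S": 1.43, "T": 0.96, "W": 0.96,
        "Y": 1.14, "V": 0.50,
    },
}
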