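"""Packaged per-residue scales and constants.

All tables are keyed by the 20 standard one-letter residue codes. Sources:

* average / monoisotopic residue masses: Expasy reference values (mass of the
  residue inside a chain, i.e. amino acid minus one water);
* Eisenberg consensus hydrophobicity scale (Eisenberg et al. 1984);
* EMBOSS pKa set for the Henderson-Hasselbalch charge curve;
* AGGRESCAN in-vivo aggregation-propensity scale (a4v, Conchillo-Sole et al.
  2007) — dimensionless, larger means more aggregation-prone.

Scales are plain dicts so callers can swap in their own.
"""

STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

# Da; residue = amino acid - H2O
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_MASS_AVERAGE: float = 18.01528
WATER_MASS_MONOISOTOPIC: float = 18.0105646863

EISENBERG_HYDROPHOBICITY: dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

HYDROPHOBICITY_SCALES: dict[str, dict[str, float]] = {
    "eisenberg": EISENBERG_HYDROPHOBICITY,
}

# side-chain pKa values plus termini; positive groups first
EMBOSS_PKA: dict[str, float] = {
    "n_term": 8.6, "c_term": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}

PKA_SETS: dict[str, dict[str, float]] = {
    "emboss": EMBOSS_PKA,
}

# AGGRESCAN in-vivo aggregation propensity per residue
A4V_SCALE: dict[str, float] = {
    "I": 1.822, "F": 1.754, "V": 1.594, "L": 1.380, "Y": 1.159,
    "W": 1.037, "M": 0.910, "C": 0.604, "A": -0.036, "T": -0.159,
    "Q": -0.276, "S": -0.294, "P": -0.334, "G": -0.535, "N": -0.776,
    "K": -0.931, "H": -1.033, "R": -1.240, "E": -1.412, "D": -1.836,
}

# van der Waals radii by element (Angstrom), Bondi-style
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
}
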