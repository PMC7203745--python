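"""Bundled chemical reference data.

Standard atomic weights (IUPAC 2021 abridged, three decimal places) for the
elements that occur in macromolecular structure files, plus the residue-name
sets and code tables the parsers and standardizers share.
"""

import logging

logger = logging.getLogger(__name__)

#: Standard atomic weights in daltons, 3-decimal precision.
ATOMIC_WEIGHTS = {
    "H": 1.008, "HE": 4.003, "LI": 6.940, "BE": 9.012, "B": 10.810,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "NE": 20.180,
    "NA": 22.990, "MG": 24.305, "AL": 26.982, "SI": 28.085, "P": 30.974,
    "S": 32.060, "CL": 35.450, "AR": 39.950, "K": 39.098, "CA": 40.078,
    "SC": 44.956, "TI": 47.867, "V": 50.942, "CR": 51.996, "MN": 54.938,
    "FE": 55.845, "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.380,
    "GA": 69.723, "GE": 72.630, "AS": 74.922, "SE": 78.971, "BR": 79.904,
    "KR": 83.798, "RB": 85.468, "SR": 87.620, "Y": 88.906, "ZR": 91.224,
    "NB": 92.906, "MO": 95.950, "RU": 101.070, "RH": 102.906, "PD": 106.420,
    "AG": 107.868, "CD": 112.414, "IN": 114.818, "SN": 118.710,
    "SB": 121.760, "TE": 127.600, "I": 126.904, "XE": 131.293,
    "CS": 132.905, "BA": 137.327, "LA": 138.905, "CE": 140.116,
    "PR": 140.908, "ND": 144.242, "SM": 150.360, "EU": 151.964,
    "GD": 157.250, "TB": 158.925, "DY": 162.500, "HO": 164.930,
    "ER": 167.259, "TM": 168.934, "YB": 173.045, "LU": 174.967,
    "HF": 178.486, "TA": 180.948, "W": 183.840, "RE": 186.207,
    "OS": 190.230, "IR": 192.217, "PT": 195.084, "AU": 196.967,
    "HG": 200.592, "TL": 204.380, "PB": 207.200, "BI": 208.980,
    "TH": 232.038, "U": 238.029,
}

#: Residue names treated as water. Configurable by mutating this set.
WATER_NAMES = {"HOH", "DOD", "WAT"}

#: Three-letter to one-letter amino-acid codes (unknown residues become "X").
CODES_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

CODES_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "U": "SEC", "O": "PYL", "X": "UNK",
}

_warned_elements = set()


def atomic_weight(element):
    """Standard atomic weight of ``element`` in daltons.

    Unknown symbols contribute 0 so malformed files remain usable; the
    first occurrence of each unknown symbol is logged as a warning.
    """
    weight = ATOMIC_WEIGHTS.get(str(element).upper())
    if weight is None:
        if element not in _warned_elements:
            logger.warning("Unknown element symbol %r: mass taken as 0", element)
            _warned_elements.add(element)
        return 0.0
    return weight
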