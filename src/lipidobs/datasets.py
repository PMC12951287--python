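"""Small bundled example datasets.

``monomer_hbond_table()`` returns the published residue-resolved
hydrogen-bond count table for a single cationic peptide adsorbed on the
nine-species Gram-positive model membrane (bonds per frame, block errors in
parentheses in the original; dashes are zeros).  It exists so the table
aggregation arithmetic can be exercised against printed marginals without
any trajectory.
"""

from __future__ import annotations

import numpy as np

from .hbonds import HBondTable

_RESIDUES = ["G_1", "I_2", "K_7", "K_18", "R_19", "K_20", "R_21"]

_MONOMER_CELLS = {
    "DPPG":  [0.01, 0.00, 0.09, 0.00, 0.00, 0.01, 0.00],
    "MAIPG": [0.07, 0.01, 0.36, 0.80, 1.44, 0.64, 1.64],
    "AIPE":  [0.01, 0.00, 0.03, 0.00, 0.00, 0.00, 0.01],
    "MAIPE": [0.03, 0.02, 0.19, 0.05, 0.02, 0.01, 0.05],
    "PAIPG": [0.04, 0.02, 0.13, 0.00, 0.14, 0.06, 0.00],
    "PAIPE": [0.00, 0.00, 0.01, 0.00, 0.00, 0.00, 0.00],
    "DPPE":  [0.01, 0.00, 0.00, 0.00, 0.01, 0.00, 0.00],
    "AIPG":  [0.19, 0.13, 0.16, 0.00, 0.35, 0.59, 0.03],
    "PAICL": [0.00, 0.00, 0.00, 0.93, 1.51, 0.58, 0.00],
}

_MONOMER_ERRS = {
    "DPPG":  [0.00, 0.00, 0.06, 0.00, 0.00, 0.01, 0.00],
    "MAIPG": [0.02, 0.00, 0.15, 0.14, 0.22, 0.15, 0.18],
    "AIPE":  [0.01, 0.00, 0.03, 0.00, 0.00, 0.00, 0.01],
    "MAIPE": [0.02, 0.01, 0.05, 0.03, 0.01, 0.01, 0.04],
    "PAIPG": [0.04, 0.02, 0.07, 0.00, 0.14, 0.05, 0.00],
    "PAIPE": [0.00, 0.00, 0.01, 0.00, 0.00, 0.00, 0.00],
    "DPPE":  [0.01, 0.00, 0.00, 0.00, 0.01, 0.00, 0.00],
    "AIPG":  [0.03, 0.06, 0.06, 0.00, 0.22, 0.17, 0.02],
    "PAICL": [0.00, 0.00, 0.00, 0.05, 0.38, 0.18, 0.00],
}

#: published per-residue totals of the same table (its SUM row)
MONOMER_RESIDUE_TOTALS = {"G_1": 0.36, "I_2": 0.17, "K_7": 0.97,
                          "K_18": 1.78, "R_19": 3.49, "K_20": 1.88,
                          "R_21": 1.73}


def monomer_hbond_table() -> HBondTable:
    """Residue x lipid-species H-bond counts for the monomer system."""
    species = list(_MONOMER_CELLS)
    counts = np.array([_MONOMER_CELLS[s] for s in species]).T  # res x sp
    errs = np.array([_MONOMER_ERRS[s] for s in species]).T
    return HBondTable(list(_RESIDUES), species, counts, errs, (0.35, 30.0))
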