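"""Physicochemical property distance between amino-acid types.

Each residue type is described by a two-component property vector
(hydrophobicity, formal charge).  The distance between two types is the
Euclidean norm of the difference of their property vectors:

    PD(x, y) = sqrt((H(x) - H(y))^2 + (Q(x) - Q(y))^2)

R and K carry +1 charge, E and D carry -1; every other residue is neutral
(histidine is treated as neutral, no pH model).  The default hydrophobicity
scale is the Wimley-White interface scale (kcal/mol); any two-column
residue->value table can be substituted.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Formal charges at neutral pH, elementary units.
CHARGE: Dict[str, int] = {aa: 0 for aa in AA_ORDER}
CHARGE.update({"R": 1, "K": 1, "E": -1, "D": -1})

#: Wimley-White interfacial hydrophobicity scale, kcal/mol
#: (water -> POPC interface transfer free energy; charged D/E/H variants
#: replaced by the values consistent with the integer charges above).
WIMLEY_WHITE_INTERFACE: Dict[str, float] = {
    "A": 0.17, "C": -0.24, "D": 1.23, "E": 2.02, "F": -1.13,
    "G": 0.01, "H": 0.17, "I": -0.31, "K": 0.99, "L": -0.56,
    "M": -0.23, "N": 0.42, "P": 0.45, "Q": 0.58, "R": 0.81,
    "S": 0.13, "T": 0.14, "V": 0.07, "W": -1.85, "Y": -0.94,
}


def load_scale(path) -> Dict[str, float]:
    """Read a two-column TSV (residue, hydrophobicity) into a scale table."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["aa", "h"])
    scale = {str(a).strip().upper(): float(h) for a, h in zip(df["aa"], df["h"])}
    for aa, value in scale.items():
        if len(aa) != 1 or aa not in AA_ORDER:
            raise ValueError(f"unknown residue symbol in scale table: {aa!r}")
        if not math.isfinite(value):
            raise ValueError(f"non-finite hydrophobicity for {aa}")
    return scale


def property_vector(aa: str, scale: Mapping[str, float] | None = None) -> Tuple[float, int]:
    """(hydrophobicity, charge) for a one-letter residue type."""
    aa = aa.upper()
    scale = WIMLEY_WHITE_INTERFACE if scale is None else scale
    if aa not in scale or aa not in CHARGE:
        raise KeyError(f"unknown residue symbol: {aa!r}")
    return float(scale[aa]), CHARGE[aa]


def pd_distance(x: str, y: str, scale: Mapping[str, float] | None = None) -> float:
    """Euclidean property distance between residue types ``x`` and ``y``.

    Symmetric, non-negative, zero iff the two property vectors coincide.
    """
    hx, qx = property_vector(x, scale)
    hy, qy = property_vector(y, scale)
    return math.sqrt((hx - hy) ** 2 + (qx - qy) ** 2)


def pd_matrix(scale: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Full 20x20 property-distance matrix over :data:`AA_ORDER`."""
    aas = list(AA_ORDER)
    mat = np.zeros((20, 20))
    for i, a in enumerate(aas):
        for j, b in enumerate(aas):
            mat[i, j] = pd_distance(a, b, scale)
    return pd.DataFrame(mat, index=aas, columns=aas)
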