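"""Natural isotope abundances used for labeling simulation and MID correction.

Values are IUPAC representative abundances. Each entry maps an element symbol
to the fractional abundance of its nominal-mass isotopologues ``[M, M+1, ...]``.
Only mass shifts are tracked (nominal-mass resolution), so 17O and 18O occupy
the M+1 and M+2 slots of oxygen.
"""

from __future__ import annotations

import numpy as np

# Abundance of the M+1 heavy isotope for the two biologically tracked elements.
C13_ABUNDANCE = 0.0107
H2_ABUNDANCE = 0.000115

# Per-element natural mass-shift distributions for correction of derivatized ions.
ELEMENT_MID: dict[str, np.ndarray] = {
    "C": np.array([1.0 - C13_ABUNDANCE, C13_ABUNDANCE]),
    "H": np.array([1.0 - H2_ABUNDANCE, H2_ABUNDANCE]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "Si": np.array([0.92223, 0.04685, 0.03092]),
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0001]),
}

# Nominal atomic masses, used to sanity-check fragment formulas against m/z.
NOMINAL_MASS = {"C": 12, "H": 1, "N": 14, "O": 16, "Si": 28, "S": 32}


def heavy_fraction(element: str) -> float:
    """Probability that a single atom of *element* carries a +1 mass shift."""
    if element == "C":
        return C13_ABUNDANCE
    if element == "H":
        return H2_ABUNDANCE
    raise KeyError(f"no tracked heavy isotope for element {element!r}")
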