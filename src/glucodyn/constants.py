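"""Physical constants for mass-spectrometric annotation.

Monoisotopic masses of the most abundant isotope of each element, in
unified atomic mass units (Da), from the standard atomic-mass tables
(CODATA/AME2020 values, truncated at 1e-7 Da).  Cation adduct masses
include the loss of one electron, so that

    m/z([M+X]+) = monoisotopic(M) + ADDUCT_MASSES["M+X"]

CONSTANTS_VERSION bumps whenever a value in this file changes.
"""

CONSTANTS_VERSION = "2024.1"

ELECTRON_MASS = 0.0005485799  # Da

#: Monoisotopic mass of the principal isotope, Da.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,  # exact by definition of the unified atomic mass unit
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.9737615120,
    "S": 31.9720706912,
    "Na": 22.9897692820,
    "K": 38.9637064864,
    "I": 126.9044719,
    "Cl": 34.9688527,
    "F": 18.9984031627,
}

#: Mass added to the neutral monoisotopic mass M for each singly charged
#: cationic adduct (cation mass minus one electron).
ADDUCT_MASSES: dict[str, float] = {
    "M+H": MONOISOTOPIC_MASSES["H"] - ELECTRON_MASS,
    "M+Na": MONOISOTOPIC_MASSES["Na"] - ELECTRON_MASS,
    "M+K": MONOISOTOPIC_MASSES["K"] - ELECTRON_MASS,
    "M+2Na-H": 2 * MONOISOTOPIC_MASSES["Na"]
    - MONOISOTOPIC_MASSES["H"]
    - ELECTRON_MASS,
}
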