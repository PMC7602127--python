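"""Monoisotopic atomic masses and ion-physics constants.

Masses are those of the most abundant naturally occurring isotope, on the
unified atomic mass scale (12C = 12 exactly), in Da. Values follow the
IUPAC/CODATA recommendations at sub-ppm precision, which is far below the
mass accuracy of any instrument this package targets.
"""

#: Monoisotopic mass of the most abundant isotope, per element symbol (Da).
MONOISOTOPIC: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031627,
    "Na": 22.98976928,
    "Mg": 23.985041697,
    "Si": 27.9769265347,
    "P": 30.97376151,
    "S": 31.97207069,
    "Cl": 34.96885271,
    "K": 38.9637064864,
    "Ca": 39.962590863,
    "Fe": 55.93493633,
    "Br": 78.9183376,
    "I": 126.9044719,
}

#: Electron rest mass (Da); subtracted once per positive charge when
#: converting a neutral-molecule mass into an ion m/z.
ELECTRON_MASS: float = 0.000549

#: Mass of a hydrogen atom (Da); the unit step for hydrogen-rearrangement
#: shifts in fragment matching.
HYDROGEN_MASS: float = MONOISOTOPIC["H"]

#: Elements counted like hydrogen in ring-and-double-bond arithmetic.
HALOGENS: frozenset[str] = frozenset({"F", "Cl", "Br", "I"})
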