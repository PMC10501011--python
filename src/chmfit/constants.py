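"""Physical constants and small element tables (CODATA 2018)."""

BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM
HARTREE_TO_CM = 219474.6313632
CM_TO_HARTREE = 1.0 / HARTREE_TO_CM
HARTREE_TO_KCALMOL = 627.5094740631
AMU_TO_ME = 1822.888486209
FS_TO_AUT = 41.341373335182114

# Nuclear charges for the elements this package is exercised on.
ATOMIC_NUMBER = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}

# Standard atomic weights, amu.
ATOMIC_MASS = {
    "H": 1.00782503207, "He": 4.002602, "Li": 6.94, "Be": 9.0121831,
    "B": 10.81, "C": 12.0, "N": 14.003074, "O": 15.994915,
    "F": 18.998403, "Ne": 20.1797, "Na": 22.989769, "Mg": 24.305,
    "Al": 26.981539, "Si": 28.085, "P": 30.973762, "S": 32.06,
    "Cl": 35.45, "Ar": 39.948,
}
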