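"""Physical constants and unit conversions (CODATA-rounded).

Internal dynamics run in Hartree atomic units; user-facing geometry is in
Angstrom, masses in amu, times in fs.
"""

ANGSTROM_TO_BOHR = 1.8897261255
BOHR_TO_ANGSTROM = 1.0 / ANGSTROM_TO_BOHR
AMU_TO_ME = 1822.888486          # atomic mass unit in electron masses
HARTREE_TO_EV = 27.211386245988
AU_TIME_FS = 0.02418884326586    # one atomic time unit in fs

# most-abundant-isotope masses, amu
ISOTOPE_MASS_AMU = {
    "H": 1.007825,
    "C": 12.0,
    "N": 14.003074,
    "O": 15.994915,
    "S": 31.972071,
}

ALLOWED_ELEMENTS = frozenset(ISOTOPE_MASS_AMU)
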