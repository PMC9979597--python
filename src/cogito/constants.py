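"""Physical constants and unit conventions.

All quantities in the package follow GROMACS conventions: lengths in nm,
energies in kJ/mol, masses in g/mol, charges in elementary charge units,
angles stored in degrees in parameter tables and converted to radians for
arithmetic.
"""

#: Standard atomic weights (g/mol) used to derive bead masses from their
#: heavy-atom compositions.
ATOMIC_WEIGHTS: dict[str, float] = {
    "C": 12.0107,
    "H": 1.00794,
    "O": 15.9994,
}

#: Electric conversion factor f = 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_CONSTANT: float = 138.935458

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT: float = 8.314462618

#: Avogadro constant, mol^-1.
AVOGADRO: float = 6.02214076e23

#: Default non-bonded cut-off distance (nm) for both LJ and Coulomb terms.
DEFAULT_CUTOFF: float = 1.1
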