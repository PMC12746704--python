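"""Physical constants and unit conversions.

All internal energies are kJ/mol; entropies are J/(K mol); temperatures K.
"""

# CODATA 2018
R_J = 8.314462618          # gas constant, J/(mol K)
R_KJ = R_J / 1000.0        # gas constant, kJ/(mol K)
K_B = 1.380649e-23         # Boltzmann constant, J/K
PLANCK_H = 6.62607015e-34  # Planck constant, J s

# Unit conversion factors to kJ/mol
EV_TO_KJ = 96.4853
KCAL_TO_KJ = 4.184
HARTREE_TO_KJ = 2625.4996394799

#: Default network temperature (60 degC), K
DEFAULT_TEMPERATURE = 333.15

_TO_KJ = {
    "kJ/mol": 1.0,
    "kcal/mol": KCAL_TO_KJ,
    "eV": EV_TO_KJ,
    "Hartree": HARTREE_TO_KJ,
}


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy between kJ/mol, kcal/mol, eV and Hartree.

    Exact linear conversion; round-trips are identities up to floating point.
    """
    try:
        f = _TO_KJ[from_unit]
    except KeyError:
        raise ValueError(f"unknown energy unit: {from_unit!r}") from None
    try:
        t = _TO_KJ[to_unit]
    except KeyError:
        raise ValueError(f"unknown energy unit: {to_unit!r}") from None
    return value * f / t
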