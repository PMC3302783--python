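"""Physical constants and standard-state conventions.

Units follow the force-field convention used throughout the package:
energies in kcal/mol, lengths in Å, times in ps, temperatures in K.
"""

#: Boltzmann constant, kcal/mol/K.
KB_KCAL: float = 0.0019872041

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE: float = 300.0

#: Standard-state reference volume, Å³. One solute per 1660 Å³ corresponds to
#: the 1 M standard concentration used to anchor binding free energies.
STANDARD_VOLUME: float = 1660.0


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B·T in kcal/mol."""
    return KB_KCAL * temperature
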