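"""Physical constants in the kcal/mol, Å, e unit system."""

#: Coulomb constant k_e, kcal·Å/(mol·e²)
K_COULOMB = 332.0637

#: Boltzmann constant, kcal/(mol·K)
K_BOLTZMANN = 1.987204259e-3

#: Avogadro's number, 1/mol
N_AVOGADRO = 6.02214076e23

#: Default simulation temperature, K
DEFAULT_TEMPERATURE = 310.0


def kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT in kcal/mol (0.6160 kcal/mol at 310 K)."""
    return K_BOLTZMANN * temperature
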