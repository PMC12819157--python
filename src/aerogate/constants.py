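"""Physical constants (SI) used throughout the package."""

ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
WATER_RELATIVE_PERMITTIVITY = 78.4  # dimensionless, ~25 C

NM = 1e-9  # m per nm


def thermal_voltage(temperature_k: float) -> float:
    """kT/e in volts."""
    return BOLTZMANN * temperature_k / ELEMENTARY_CHARGE
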