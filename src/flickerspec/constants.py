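"""Physical constants used throughout the package (SI units)."""

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN = 1.380649e-23

#: Default absolute temperature, K.  Exposed because thermal energy enters
#: every spectrum; override per experiment in the configuration file.
DEFAULT_TEMPERATURE = 298.0


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """k_B * T in Joules."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    return BOLTZMANN * temperature
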