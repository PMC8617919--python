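"""Physical constants and unit conventions.

All coordinates are in angstroms and all energies in kcal/mol throughout
the package; temperature is in kelvin.
"""

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL_MOL_K: float = 0.0019872041


def thermal_energy(temperature_k: float) -> float:
    """Return k_B*T in kcal/mol for a temperature in kelvin."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return KB_KCAL_MOL_K * temperature_k
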