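"""Thermal-energy unit helpers.

All energies in this package are kcal/mol; inverse temperatures ("beta")
are therefore in mol/kcal.  Temperatures are in Kelvin.
"""

from __future__ import annotations

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_PER_MOL_K: float = 0.0019872041

#: Default temperature (K) used when thresholds are quoted in units of kT.
DEFAULT_TEMPERATURE: float = 300.0


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT in kcal/mol at the given temperature."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_PER_MOL_K * temperature


def beta_from_temperature(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse temperature 1/(kT) in mol/kcal."""
    return 1.0 / kt(temperature)
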