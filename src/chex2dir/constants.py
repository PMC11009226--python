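"""Physical constants and unit conventions.

All molar energies in this package are expressed per mole, so every
Boltzmann-type factor exp(-E/kT) is evaluated as exp(-E/(R*T)) with the
molar gas constant R.  Temperatures are stored in degrees Celsius at the
I/O surface and converted to Kelvin as K = degC + 273.15 wherever a
thermodynamic or kinetic expression needs an absolute temperature.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the constants the pipeline uses.

    Attributes
    ----------
    R:
        Molar gas constant, J mol^-1 K^-1 (CODATA).
    celsius_offset:
        Additive offset converting degrees Celsius to Kelvin.
    """

    R: float = 8.314462618
    celsius_offset: float = 273.15

    def kelvin(self, celsius: float) -> float:
        """Convert a temperature in degrees Celsius to Kelvin."""
        return celsius + self.celsius_offset


CONSTANTS = PhysicalConstants()

#: Molar gas constant, J mol^-1 K^-1.
R = CONSTANTS.R

#: Offset from degrees Celsius to Kelvin.
CELSIUS_OFFSET = CONSTANTS.celsius_offset


def celsius_to_kelvin(celsius):
    """Convert Celsius to Kelvin (scalar or array)."""
    return celsius + CELSIUS_OFFSET
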