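"""Physical constants and unit conventions.

All public interfaces use degrees for angles, picoseconds for time and
kcal/mol for energies.  Internally, energies that couple to angles
(umbrella force constants, diffusivities) are handled in radians:
force constants are kcal mol^-1 rad^-2 and diffusivities rad^2 ps^-1.
"""

import numpy as np

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL = 1.987204259e-3

#: Angular period of the flipping coordinate, degrees
PERIOD_DEG = 360.0

DEG2RAD = np.pi / 180.0
RAD2DEG = 180.0 / np.pi

#: picoseconds per second
PS_PER_S = 1.0e12


def kt_kcal(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL * temperature
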