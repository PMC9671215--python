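"""Physical constants and shared unit helpers.

All constants are CODATA 2018 values taken from :mod:`scipy.constants`.
Lengths are handled in nanometres at the API surface and converted to SI
internally; energies in joules.
"""

from __future__ import annotations

from scipy import constants as _c

#: Elementary charge [C]
ELEMENTARY_CHARGE = _c.elementary_charge
#: Boltzmann constant [J/K]
BOLTZMANN = _c.Boltzmann
#: Vacuum permittivity [F/m]
VACUUM_PERMITTIVITY = _c.epsilon_0

#: Standard laboratory temperature [K] (measurements at 25 degC)
DEFAULT_TEMPERATURE_K = 298.15

#: nm per m
NM_PER_M = 1e9


def constants_table() -> dict[str, float]:
    """Return the constants used throughout the package, keyed by name."""
    return {
        "elementary_charge_C": ELEMENTARY_CHARGE,
        "boltzmann_J_per_K": BOLTZMANN,
        "vacuum_permittivity_F_per_m": VACUUM_PERMITTIVITY,
        "default_temperature_K": DEFAULT_TEMPERATURE_K,
    }
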