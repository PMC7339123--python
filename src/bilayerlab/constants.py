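"""Physical constants and unit conversions used throughout the package."""

import scipy.constants as _const

#: Boltzmann constant, J/K
BOLTZMANN_K = _const.k
#: Elementary charge, C
ELEMENTARY_CHARGE = _const.e
#: Molar gas constant, J/(mol K)
GAS_CONSTANT_R = _const.R
#: Offset between Celsius and Kelvin scales
CELSIUS_OFFSET = 273.15
#: Default assay temperature (room temperature, 25 C), K
ROOM_TEMPERATURE_K = 298.15


def thermal_voltage_mV(temperature_K: float = ROOM_TEMPERATURE_K) -> float:
    """kT/e in millivolts at the given absolute temperature.

    At 298.15 K this is 25.69 mV, the voltage over which a Boltzmann-
    distributed monovalent ion population changes e-fold.
    """
    if temperature_K <= 0:
        raise ValueError(f"temperature_K must be > 0, got {temperature_K}")
    return 1e3 * BOLTZMANN_K * temperature_K / ELEMENTARY_CHARGE


def celsius_to_kelvin(t_C):
    return t_C + CELSIUS_OFFSET


def kelvin_to_celsius(t_K):
    return t_K - CELSIUS_OFFSET
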