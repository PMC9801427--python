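"""Unit conversions and physical constants used throughout the package."""

from .exceptions import InvalidInputError

#: Molar gas constant, kJ mol^-1 K^-1 (CODATA 2018, exact).
R_GAS = 8.31446261815324e-3

#: 0 degrees Celsius in kelvin.
ZERO_CELSIUS = 273.15


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + ZERO_CELSIUS


def kelvin_to_celsius(t_kelvin: float) -> float:
    return t_kelvin - ZERO_CELSIUS


def molar_to_mg_per_ml(conc_molar: float, molar_mass: float) -> float:
    """Convert a molar concentration to a mass concentration.

    Parameters
    ----------
    conc_molar
        Concentration in mol/L.
    molar_mass
        Molar mass in g/mol.

    Returns
    -------
    float
        Concentration in mg/mL (== g/L).
    """
    if conc_molar < 0 or molar_mass <= 0:
        raise InvalidInputError("concentration must be >= 0 and molar mass > 0")
    return conc_molar * molar_mass
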