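"""Gas-transfer velocities, equilibrium CH4 and diffusive flux.

The gas-transfer velocity k600 follows the slope-velocity scaling model for
streams, k600 = S*V*2841 + 2.02 (m/day), standardised to a Schmidt number of
600. Conversion to the CH4-specific velocity uses the freshwater Schmidt
polynomial at modelled water temperature; equilibrium concentration follows
Henry's law with a zero-salinity solubility fit and a barometric pressure
correction for site elevation. Diffusive flux is Fick's law on the excess
dissolved CH4. All functions are vectorised over numpy arrays.
"""

from __future__ import annotations

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "k600_from_hydraulics",
    "water_temp_from_air",
    "schmidt_ch4",
    "k_ch4_from_k600",
    "barometric_pressure",
    "equilibrium_concentration",
    "diffusive_flux",
]


def k600_from_hydraulics(slope, velocity, constants: PhysicalConstants = DEFAULT_CONSTANTS,
                         slope_coef=None, intercept=None):
    """Gas-transfer velocity k600 (m/day) from channel slope and velocity.

    k600 = S * V * slope_coef + intercept, with S in m/m and V in m/s.
    ``slope_coef`` and ``intercept`` override the constants (used by the
    Monte Carlo stage, which samples them from their published s.d.).
    """
    slope = np.asarray(slope, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if np.any(slope < 0) or np.any(velocity < 0):
        raise ValueError("slope and velocity must be non-negative")
    a = constants.k600_slope if slope_coef is None else slope_coef
    b = constants.k600_intercept if intercept is None else intercept
    return slope * velocity * a + b


def water_temp_from_air(t_air, slope: float = 1.0, intercept: float = 0.0,
                        floor: float = 0.0):
    """Monthly water temperature (deg C) from air temperature.

    A configurable linear air-to-water mapping, floored at ``floor`` (0 deg C
    by default: rivers below freezing are treated as ice-covered upstream of
    this function, via the ice-free area fraction).
    """
    t_air = np.asarray(t_air, dtype=float)
    return np.maximum(slope * t_air + intercept, floor)


def schmidt_ch4(t_water, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Schmidt number of CH4 in fresh water at ``t_water`` deg C.

    Polynomial fit valid for 0-40 deg C; strictly decreasing in temperature.
    """
    t = np.asarray(t_water, dtype=float)
    if np.any(t < 0.0) or np.any(t > 40.0):
        raise ValueError("water temperature outside the 0-40 degC validity range")
    c = constants.schmidt_coeffs
    return c[0] + c[1] * t + c[2] * t**2 + c[3] * t**3 + c[4] * t**4


def k_ch4_from_k600(k600, sc_ch4):
    """Convert k600 to the CH4-specific transfer velocity (m/day).

    k_CH4 = k600 * (Sc_CH4 / 600)^(-1/2); identical to k600 when Sc = 600.
    """
    k600 = np.asarray(k600, dtype=float)
    sc_ch4 = np.asarray(sc_ch4, dtype=float)
    return k600 * (sc_ch4 / 600.0) ** -0.5


def barometric_pressure(elevation_m, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Atmospheric pressure (atm) at elevation, isothermal exponential profile."""
    elevation_m = np.asarray(elevation_m, dtype=float)
    if np.any(elevation_m < -500.0):
        raise ValueError("elevation below -500 m a.s.l. is not supported")
    return np.exp(-elevation_m / constants.scale_height_m)


def equilibrium_concentration(t_water, elevation_m=0.0,
                              constants: PhysicalConstants = DEFAULT_CONSTANTS,
                              atm_ch4_ppm=None):
    """Equilibrium dissolved CH4 (mmol/m^3) for water in contact with air.

    Henry's-law solubility at the water temperature times the atmospheric
    partial pressure of CH4 (mixing ratio x pressure from elevation). The
    zero-salinity solubility fit takes the atmospheric mole fraction and
    returns nmol/L at 1 atm, converted here to mmol/m^3
    (1 nmol/L = 1e-3 mmol/m^3).
    """
    t = np.asarray(t_water, dtype=float)
    ppm = constants.atm_ch4_ppm if atm_ch4_ppm is None else atm_ch4_ppm
    a1, a2, a3, a4 = constants.solubility_coeffs
    tk = t + 273.15
    ln_c = (np.log(ppm * 1e-6) + a1 + a2 * (100.0 / tk)
            + a3 * np.log(tk / 100.0) + a4 * (tk / 100.0))
    c_nmol_l = np.exp(ln_c)
    pressure = barometric_pressure(elevation_m, constants)
    return c_nmol_l * 1e-3 * pressure


def diffusive_flux(c_water, c_eq, k_ch4):
    """Diffusive CH4 flux (mmol m^-2 day^-1) by Fick's law.

    flux = k_CH4 * (c_w - c_eq). Negative values (influx from the atmosphere
    into undersaturated water) are retained, not clipped.
    """
    c_water = np.asarray(c_water, dtype=float)
    if np.any(c_water < 0):
        raise ValueError("dissolved concentration must be non-negative")
    return np.asarray(k_ch4, dtype=float) * (c_water - np.asarray(c_eq, dtype=float))
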