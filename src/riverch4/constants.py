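"""Physical constants and empirical coefficients used across the pipeline.

Every number that enters the flux calculation lives here so a run can log the
exact parameter set it used. The gas-transfer model coefficients carry their
published standard deviations because the Monte Carlo stage samples them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Molar mass of CH4, g/mol.
MOLAR_MASS_CH4 = 16.04

#: Boltzmann constant in electron-volts per kelvin.
BOLTZMANN_EV = 8.617e-5

#: Days in each calendar month of a non-leap year.
DAYS_PER_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)

#: Wanninkhof (2014) freshwater Schmidt-number polynomial for CH4,
#: Sc = a0 + a1*t + a2*t^2 + a3*t^3 + a4*t^4 with t in deg C.
SCHMIDT_CH4_COEFFS = (1909.4, -120.78, 4.1555, -0.080578, 0.00065777)

#: Wiesenburg & Guinasso (1979) zero-salinity solubility fit for CH4:
#: ln C = ln f_G + A1 + A2*(100/T) + A3*ln(T/100) + A4*(T/100),
#: C in nmol/L for f_G in ppmv at 1 atm moist air.
SOLUBILITY_CH4_COEFFS = (-417.5053, 599.8626, 380.3636, -62.0764)


@dataclass(frozen=True)
class PhysicalConstants:
    """Constant set for gas exchange and flux upscaling.

    Parameters
    ----------
    k600_slope : float
        Coefficient on S*V in the slope-velocity gas-transfer model, m/day
        per (m/m * m/s). Published value 2841 with s.d. 107.
    k600_intercept : float
        Intercept of the same model, m/day. Published value 2.02, s.d. 0.209.
    atm_ch4_ppm : float
        Atmospheric CH4 mixing ratio, ppm by volume (2010-2020 mean).
    t_ref_c : float
        Reference temperature Tc for Boltzmann standardisation, deg C.
    boltzmann_ev : float
        Boltzmann constant, eV/K.
    scale_height_m : float
        Scale height of the isothermal barometric formula used to derive
        atmospheric pressure from elevation, m.
    """

    k600_slope: float = 2841.0
    k600_slope_sd: float = 107.0
    k600_intercept: float = 2.02
    k600_intercept_sd: float = 0.209
    atm_ch4_ppm: float = 1.83
    t_ref_c: float = 15.0
    boltzmann_ev: float = BOLTZMANN_EV
    scale_height_m: float = 8500.0
    molar_mass_ch4: float = MOLAR_MASS_CH4
    schmidt_coeffs: tuple = field(default=SCHMIDT_CH4_COEFFS)
    solubility_coeffs: tuple = field(default=SOLUBILITY_CH4_COEFFS)


DEFAULT_CONSTANTS = PhysicalConstants()
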