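"""Apparent activation energy of diffusive CH4 emissions.

Fluxes are regressed on Boltzmann-standardised inverse temperature
x = 1/(kB*Tc) - 1/(kB*T) (units 1/eV, zero at the 15 degC reference), so the
slope of ln(flux) on x is the apparent activation energy E_M in eV and is
invariant to multiplicative rescaling of the fluxes. Fits are made per site
(for sites with enough observations) and pooled over all observations, and
the distribution of site E_M can be compared against reference values from
other ecosystem types with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .constants import BOLTZMANN_EV, DEFAULT_CONSTANTS, PhysicalConstants

log = logging.getLogger(__name__)

__all__ = ["standardize_temperature", "site_activation_energies",
           "compare_em_distributions"]


def standardize_temperature(t_water_c, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Boltzmann-standardised temperature x (1/eV), zero at Tc = 15 degC.

    x = 1/(kB*Tc) - 1/(kB*T) with T in kelvin; increasing in temperature.
    """
    t = np.asarray(t_water_c, dtype=float)
    if np.any(t <= -273.15):
        raise ValueError("temperature below absolute zero")
    tk = t + 273.15
    tr = constants.t_ref_c + 273.15
    kb = constants.boltzmann_ev
    return 1.0 / (kb * tr) - 1.0 / (kb * tk)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS: slope, intercept, slope standard error."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    slope = ((x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    se = np.sqrt((resid**2).sum() / (n - 2) / sxx) if n > 2 else np.nan
    return float(slope), float(intercept), float(se)


def site_activation_energies(observations: pd.DataFrame, min_n: int = 20,
                             flux_col: str = "flux_diff", t_col: str = "t_water",
                             site_col: str = "site_id",
                             constants: PhysicalConstants = DEFAULT_CONSTANTS,
                             ) -> tuple[pd.DataFrame, dict]:
    """Per-site and pooled Boltzmann-standardised flux regressions.

    Sites with more than ``min_n`` usable observations get an individual
    fit; the pooled fit uses every usable observation. Non-positive or
    missing fluxes and missing temperatures are excluded (counts reported).
    Returns (fits, info): fits has columns ``site_id, n_obs, e_m, intercept,
    slope_se`` with the pooled row labelled ``"pooled"``.
    """
    usable = observations[[site_col, flux_col, t_col]].copy()
    n_input = len(usable)
    usable = usable.dropna()
    n_nonpos = int((usable[flux_col] <= 0).sum())
    usable = usable[usable[flux_col] > 0]
    info = {"n_input": n_input, "n_used": int(len(usable)), "n_nonpositive": n_nonpos}
    if len(usable) < 3:
        log.warning("fewer than 3 usable observations; no thermal fits")
        return pd.DataFrame(columns=["site_id", "n_obs", "e_m", "intercept",
                                     "slope_se"]), info

    usable["x"] = standardize_temperature(usable[t_col].to_numpy(), constants)
    usable["ln_f"] = np.log(usable[flux_col].to_numpy(dtype=float))

    rows = []
    for site, grp in usable.groupby(site_col):
        if len(grp) <= min_n:
            continue
        x, y = grp["x"].to_numpy(), grp["ln_f"].to_numpy()
        if np.ptp(x) == 0:
            continue
        slope, intercept, se = _ols_slope(x, y)
        rows.append({"site_id": site, "n_obs": len(grp), "e_m": slope,
                     "intercept": intercept, "slope_se": se})
    if not rows:
        log.warning("no site qualifies for an individual fit (min_n=%d)", min_n)
    slope, intercept, se = _ols_slope(usable["x"].to_numpy(), usable["ln_f"].to_numpy())
    rows.append({"site_id": "pooled", "n_obs": len(usable), "e_m": slope,
                 "intercept": intercept, "slope_se": se})
    return pd.DataFrame(rows), info


def compare_em_distributions(river_em, reference_em, grid=None,
                             n_grid: int = 200) -> dict:
    """Compare two E_M distributions: rank-sum test, medians/IQRs, KDEs.

    Returns the two-sided Wilcoxon rank-sum statistic and p-value, per-group
    median and interquartile range, and Gaussian kernel density estimates on
    a shared grid (as a DataFrame under ``"density"``).
    """
    a = np.asarray(river_em, dtype=float)
    b = np.asarray(reference_em, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two E_M values")
    stat, p = stats.ranksums(a, b)

    def _summary(v):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {"median": float(med), "iqr": (float(q1), float(q3)), "n": int(len(v))}

    if grid is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        pad = 0.25 * (hi - lo if hi > lo else 1.0)
        grid = np.linspace(lo - pad, hi + pad, n_grid)
    grid = np.asarray(grid, dtype=float)
    density = pd.DataFrame({"grid": grid})
    for name, v in (("rivers", a), ("reference", b)):
        if np.ptp(v) > 0:
            density[name] = stats.gaussian_kde(v)(grid)
        else:
            density[name] = np.nan
    return {"statistic": float(stat), "p_value": float(p),
            "rivers": _summary(a), "reference": _summary(b), "density": density}
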