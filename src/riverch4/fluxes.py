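"""Flux engine: per-reach-month diffusive emissions, a-posteriori
corrections, upscaled totals and validation against measured fluxes.

Upscaling the product k * (c_w - c_eq) over whole reaches can manufacture
fluxes larger than the dissolved stock advected through the reach, most
visibly in steep channels where k is huge but concentrations are near
equilibrium. Three optional corrections address this artefact:

``cap_k``
    cap the transfer velocity at 35 m/day, where bubble-mediated exchange
    starts to dominate;
``cap_flux``
    cap flux rates above mean + 2 s.d. of the (uncorrected) rate population;
``supply_limited``
    shrink k so the 95% gas footprint length F_L = 3*V/K (K = k/D, per day)
    never falls short of the reach length, i.e. a reach can evade at most
    the pool that advection delivers. This is the default reported option.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from . import gas
from .constants import DAYS_PER_MONTH, DEFAULT_CONSTANTS, PhysicalConstants
from .hydrology import DEFAULT_COEFFS, HydraulicCoefficients, hydraulic_geometry, latitudinal_bins

log = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0

CORRECTION_OPTIONS = ("none", "cap_k", "cap_flux", "supply_limited")


def footprint_length(v_ms, k_mday, d_m):
    """95% gas footprint length F_L (m): the upstream distance over which
    ~95% of the dissolved gas would evade.

    F_L = 3 * V / K with K = k/D the reaeration coefficient (per day) and V
    expressed in m/day. Doubling depth or halving k doubles the footprint.
    """
    v = np.asarray(v_ms, dtype=float) * SECONDS_PER_DAY
    k = np.asarray(k_mday, dtype=float)
    d = np.asarray(d_m, dtype=float)
    if np.any(k <= 0) or np.any(d <= 0):
        raise ValueError("footprint length requires positive k and depth")
    return 3.0 * v / (k / d)


def correct_supply_limited(k_mday, v_ms, d_m, reach_length_m):
    """Supply-limitation correction of the gas-transfer velocity.

    Where the footprint length is shorter than the reach (F_L < R_L), the
    modelled concentration cannot be sustained over the whole reach and the
    computed evasion exceeds the available pool; k is then reduced so that
    F_L = R_L exactly: k = 3 * V_daily * D / R_L. Equivalently
    ``min(k, 3*V_daily*D/R_L)``, which never increases k and is idempotent.
    """
    k = np.asarray(k_mday, dtype=float)
    v_daily = np.asarray(v_ms, dtype=float) * SECONDS_PER_DAY
    d = np.asarray(d_m, dtype=float)
    r_l = np.asarray(reach_length_m, dtype=float)
    if np.any(r_l <= 0):
        raise ValueError("reach length must be positive")
    return np.minimum(k, 3.0 * v_daily * d / r_l)


def correct_cap_k(k_mday, cap: float = 35.0):
    """Cap the gas-transfer velocity at ``cap`` m/day (default 35, the
    threshold above which bubble-mediated fluxes begin to dominate)."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return np.minimum(np.asarray(k_mday, dtype=float), cap)


def correct_cap_flux(flux_rates):
    """Cap flux rates above mean + 2 s.d. of the uncorrected population.

    The threshold is computed once, on the full uncorrected population
    passed in; negative (influx) rates are never modified. A population of
    fewer than two values, or with zero spread, passes through unchanged.
    """
    rates = np.asarray(flux_rates, dtype=float)
    if rates.size < 2:
        warnings.warn("cap_flux needs at least two values; returning input unchanged")
        return rates.copy()
    threshold = rates.mean() + 2.0 * rates.std(ddof=0)
    return np.where(rates > threshold, threshold, rates)


def _flux_rates(table: pd.DataFrame, correction: str, k_cap: float,
                cap_flux_per_month: bool) -> pd.DataFrame:
    """Apply the chosen correction and compute flux rates on a joined
    reach-month table carrying k_ch4, v_ms, d_m, length_m, c_hat, c_eq."""
    k = table["k_ch4"].to_numpy(dtype=float)
    if correction == "cap_k":
        k_used = correct_cap_k(k, cap=k_cap)
    elif correction == "supply_limited":
        k_used = correct_supply_limited(k, table["v_ms"], table["d_m"], table["length_m"])
    else:
        k_used = k.copy()
    rate = gas.diffusive_flux(table["c_hat"], table["c_eq"], k_used)
    if correction == "cap_flux":
        if cap_flux_per_month:
            rate = (pd.Series(rate, index=table.index)
                    .groupby(table["month"]).transform(lambda s: correct_cap_flux(s.to_numpy()))
                    .to_numpy())
        else:
            rate = correct_cap_flux(rate)
    out = table.copy()
    out["k_used"] = k_used
    out["flux_rate"] = rate
    out["corrected"] = ~np.isclose(k_used, k) | ~np.isclose(rate, gas.diffusive_flux(
        table["c_hat"], table["c_eq"], k_used))
    out["correction_option"] = correction
    return out


def upscale(reaches: pd.DataFrame, concentrations: pd.DataFrame,
            correction: str = "supply_limited",
            constants: PhysicalConstants = DEFAULT_CONSTANTS,
            coeffs: HydraulicCoefficients = DEFAULT_COEFFS,
            k_cap: float = 35.0, cap_flux_per_month: bool = True,
            air_water=(1.0, 0.0)) -> tuple[pd.DataFrame, dict]:
    """Per-reach-month diffusive CH4 emissions and aggregated totals.

    Parameters
    ----------
    reaches : DataFrame
        Wide reach table (see :mod:`riverch4.hydrology`), including monthly
        air temperature columns ``tair_01..tair_12``.
    concentrations : DataFrame
        Columns ``reach_id, month, c_hat`` (mmol/m^3), optionally ``c_sd``.
    correction : str
        One of ``none | cap_k | cap_flux | supply_limited``.
    air_water : tuple
        (slope, intercept) of the linear air-to-water temperature mapping.

    Returns
    -------
    (fluxes, totals)
        ``fluxes`` has one row per reach-month with rate (mmol m^-2 d^-1),
        k used, footprint length and emission (g CH4/month). ``totals`` is a
        dict with the global total (Tg CH4/yr), per-month totals and
        per-latitudinal-band totals (10 degree bins).
    """
    if correction not in CORRECTION_OPTIONS:
        raise ValueError(f"unknown correction {correction!r}; expected one of {CORRECTION_OPTIONS}")
    hyd = hydraulic_geometry(reaches, coeffs)
    static_cols = ["reach_id", "slope", "elevation_m", "latitude", "length_m"]
    table = hyd.merge(reaches[static_cols], on="reach_id", how="left")

    tair_cols = [f"tair_{m:02d}" for m in range(1, 13)]
    if all(c in reaches.columns for c in tair_cols):
        tair = reaches[["reach_id"] + tair_cols].melt(
            id_vars="reach_id", var_name="_m", value_name="t_air")
        tair["month"] = tair["_m"].str.slice(5).astype(int)
        table = table.merge(tair[["reach_id", "month", "t_air"]], on=["reach_id", "month"])
    else:
        raise ValueError("reach table lacks monthly air temperature columns tair_01..tair_12")

    table["t_water"] = gas.water_temp_from_air(table["t_air"], *air_water)
    table["k600"] = gas.k600_from_hydraulics(table["slope"], table["v_ms"], constants)
    table["sc_ch4"] = gas.schmidt_ch4(table["t_water"], constants)
    table["k_ch4"] = gas.k_ch4_from_k600(table["k600"], table["sc_ch4"])
    table["c_eq"] = gas.equilibrium_concentration(table["t_water"], table["elevation_m"], constants)

    merged = table.merge(concentrations[["reach_id", "month", "c_hat"]],
                         on=["reach_id", "month"], how="left")
    if merged["c_hat"].isna().any():
        gaps = merged.loc[merged["c_hat"].isna(), ["reach_id", "month"]]
        raise ValueError("missing modelled concentration for reach-months: "
                         f"{gaps.head(10).to_dict('records')}"
                         + (" ..." if len(gaps) > 10 else ""))

    out = _flux_rates(merged, correction, k_cap, cap_flux_per_month)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["f_l_m"] = np.where(
            (out["k_used"] > 0) & (out["d_m"] > 0),
            3.0 * out["v_ms"] * SECONDS_PER_DAY / (out["k_used"] / out["d_m"]), np.nan)
    days = out["month"].map(lambda m: DAYS_PER_MONTH[m - 1])
    out["emission_g"] = (out["flux_rate"] * out["effective_area_m2"] * days
                         * constants.molar_mass_ch4 * 1e-3)
    totals = summarize_totals(out)
    cols = ["reach_id", "month", "latitude", "q", "v_ms", "w_m", "d_m",
            "effective_area_m2", "t_water", "k600", "k_ch4", "k_used", "c_eq",
            "c_hat", "flux_rate", "corrected", "correction_option", "f_l_m",
            "emission_g"]
    return out[cols], totals


def summarize_totals(fluxes: pd.DataFrame, bin_width: float = 10.0) -> dict:
    """Global, monthly and latitudinal-band emission totals (Tg CH4/yr)."""
    to_tg = 1e-12
    by_month = fluxes.groupby("month")["emission_g"].sum() * to_tg
    bands = latitudinal_bins(fluxes, "emission_g", bin_width=bin_width)
    band_annual = bands.groupby(["band_lo", "band_hi"], as_index=False)["emission_g"].sum()
    return {
        "global_tg_per_yr": float(fluxes["emission_g"].sum() * to_tg),
        "by_month_tg": {int(m): float(v) for m, v in by_month.items()},
        "by_band_tg": [
            {"band_lo": float(r.band_lo), "band_hi": float(r.band_hi),
             "emission_tg": float(r.emission_g * to_tg)}
            for r in band_annual.itertuples()
        ],
    }


def validate_against_measured(fluxes: pd.DataFrame, observations: pd.DataFrame,
                              reaches: pd.DataFrame,
                              k_ratio_window=(0.5, 1.5), snap_dist_m: float = 500.0,
                              excluded_k_methods=("other", "not determined")) -> dict:
    """Regress log modelled flux on log measured flux for comparable sites.

    Observations with unclear k600 methods are excluded; sites are snapped
    to reaches within ``snap_dist_m``; multiple observations per reach-month
    are averaged; only pairs whose modelled k600 is within
    ``k_ratio_window`` times the measured k600 are kept, so the comparison
    isolates the concentration signal from gas-exchange mismatch. Returns
    slope, intercept, R^2 and n of the OLS fit.
    """
    from .observations import snap_sites

    obs = observations.copy()
    obs = obs[obs["flux_diff"].notna()]
    if "k_method" in obs.columns:
        obs = obs[~obs["k_method"].isin(excluded_k_methods)]
    obs = obs[obs["k600_measured"].notna()]

    if len(obs) < 3:
        raise ValueError(f"only {len(obs)} observations usable; need >= 3 matched pairs")
    mapping = snap_sites(obs, reaches, max_dist_m=snap_dist_m)
    mapped = mapping[mapping["mapped"]]
    obs = obs.merge(mapped[["site_id", "reach_id"]], on="site_id", how="inner")
    obs["month"] = pd.to_datetime(obs["date"]).dt.month
    agg = obs.groupby(["reach_id", "month"], as_index=False).agg(
        flux_measured=("flux_diff", "mean"), k600_measured=("k600_measured", "mean"))

    joined = agg.merge(fluxes[["reach_id", "month", "flux_rate", "k600"]],
                       on=["reach_id", "month"], how="inner")
    ratio = joined["k600"] / joined["k600_measured"]
    joined = joined[(ratio >= k_ratio_window[0]) & (ratio <= k_ratio_window[1])]
    joined = joined[(joined["flux_measured"] > 0) & (joined["flux_rate"] > 0)]
    if len(joined) < 3:
        raise ValueError(f"only {len(joined)} matched pairs after filtering; need >= 3")

    import statsmodels.api as sm
    x = np.log(joined["flux_measured"].to_numpy())
    y = np.log(joined["flux_rate"].to_numpy())
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return {"slope": float(fit.params[1]), "intercept": float(fit.params[0]),
            "r2": float(fit.rsquared), "n": int(len(joined))}
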