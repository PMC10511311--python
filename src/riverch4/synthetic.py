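"""Synthetic river networks, predictor tables and observation tables with
known ground truth.

The generator emulates the three inputs of the pipeline — a reach-scale
hydrography with monthly discharge, a per-reach-month predictor table, and a
site-visit observation table — so that every stage can be tested end to end
against planted truth: the coefficients of the concentration model, the
apparent activation energy of diffusive fluxes, and the log-log
ebullition-diffusion relation.

Distributional choices are pragmatic emulation, not claims about any real
dataset: tree-structured topology with discharge accumulating downstream,
lognormal headwater runoff, sinusoidal seasonality, slopes declining with
stream order, ice phenology tied to latitude through a simple air
temperature climatology, and a median reach length of ~6.8 km.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import gas
from .constants import BOLTZMANN_EV, DEFAULT_CONSTANTS

MONTHS = np.arange(1, 13)

#: Default ground-truth coefficients of the log-concentration model, applied
#: to z-scored predictors. Signs follow field expectation: organic-matter
#: supply and wetness raise CH4; slope, elevation (turbulence, thin soils)
#: lower it.
DEFAULT_CONC_COEFFS = {
    "soil_carbon": 0.5,
    "wetland_cover": 0.4,
    "npp": 0.3,
    "precip": 0.2,
    "t_air": 0.15,
    "human_pop": 0.2,
    "slope_log": -0.5,
    "elevation_m": -0.2,
}

#: Concentration multipliers for site categories excluded from modelling
#: (human or thermokarst point influences inflate dissolved CH4).
CATEGORY_MULTIPLIERS = {
    "normal": 1.0, "below_wwtp": 8.0, "ditch": 5.0, "below_dam": 3.0,
    "fracking": 4.0, "canal": 4.0, "glacial_terminus": 0.5, "thaw_slump": 6.0,
}


class SyntheticConfig(BaseModel):
    """Ground truth and sampling design of a synthetic study."""

    model_config = ConfigDict(extra="forbid")

    n_reaches: int = Field(50, gt=0)
    seed: int = 42
    latitude_span: tuple[float, float] = (-15.0, 70.0)
    # hydrology
    runoff_log_mean: float = -1.0       # ln m^3/s of headwater local discharge
    runoff_log_sd: float = 1.0
    seasonal_amplitude: float = Field(0.4, ge=0, lt=1)
    reach_length_log_median_m: float = 6800.0
    q_cv_mean: float = 0.3
    # concentration truth (log space, z-scored predictors)
    conc_intercept_ln: float = float(np.log(0.3))   # ~0.3 mmol/m^3 baseline
    conc_coeffs: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_CONC_COEFFS))
    conc_noise_sd: float = Field(0.5, ge=0)
    # flux truth
    true_e_m: float = 0.14              # eV, apparent activation energy
    flux_noise_sd: float = Field(0.3, ge=0)
    ebullition_slope: float = 1.0       # ln-ln relation, near the 1:1 line
    ebullition_intercept: float = 0.0
    ebullition_noise_sd: float = Field(1.0, ge=0)
    # observation design
    n_observations: int = Field(500, gt=0)
    mean_revisits: float = Field(3.0, gt=0)
    time_series_frac: float = Field(0.05, ge=0, le=1)   # sites with long records
    time_series_revisits: float = Field(40.0, gt=0)
    site_jitter_m: float = 200.0
    category_mix: dict[str, float] = Field(default_factory=lambda: {
        "normal": 0.85, "below_wwtp": 0.03, "ditch": 0.03, "below_dam": 0.03,
        "fracking": 0.02, "canal": 0.02, "glacial_terminus": 0.01, "thaw_slump": 0.01,
    })

    def ground_truth(self) -> dict:
        return {
            "conc_intercept_ln": self.conc_intercept_ln,
            "conc_coeffs": dict(self.conc_coeffs),
            "conc_noise_sd": self.conc_noise_sd,
            "true_e_m": self.true_e_m,
            "ebullition_slope": self.ebullition_slope,
            "ebullition_intercept": self.ebullition_intercept,
            "seed": self.seed,
        }


def _air_temperature(latitude, month):
    """Simple monthly air-temperature climatology (deg C) by latitude."""
    lat = np.asarray(latitude, dtype=float)
    month = np.asarray(month, dtype=float)
    peak = np.where(lat >= 0, 7.0, 1.0)  # warmest month by hemisphere
    amplitude = 5.0 + 0.3 * np.abs(lat)
    return 27.0 - 0.45 * np.abs(lat) + amplitude * np.cos(2 * np.pi * (month - peak) / 12.0)


def _strahler_orders(downstream: np.ndarray) -> np.ndarray:
    n = len(downstream)
    children: list[list[int]] = [[] for _ in range(n)]
    for i, d in enumerate(downstream):
        if d >= 0:
            children[d].append(i)
    order = np.zeros(n, dtype=int)

    def visit(i):
        stack, post = [i], []
        while stack:
            node = stack.pop()
            post.append(node)
            stack.extend(children[node])
        for node in reversed(post):
            if not children[node]:
                order[node] = 1
            else:
                c = sorted((order[c] for c in children[node]), reverse=True)
                order[node] = c[0] + 1 if len(c) > 1 and c[1] == c[0] else c[0]

    roots = [i for i, d in enumerate(downstream) if d < 0]
    for r in roots:
        visit(r)
    return order


def generate_network(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a tree-structured reach table with monthly hydrology.

    Discharge accumulates downstream (a reach's annual mean is at least the
    sum of its direct tributaries'), slopes decline with stream order on
    average, ice-free fractions follow the latitude-dependent temperature
    climatology, and each reach carries a representative midpoint
    coordinate. Deterministic for a given config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reaches
    downstream = np.full(n, -1, dtype=int)
    for i in range(1, n):
        downstream[i] = rng.integers(0, i)
    order = _strahler_orders(downstream)

    # tree depth from outlet, for elevation
    depth = np.zeros(n, dtype=int)
    for i in range(1, n):
        depth[i] = depth[downstream[i]] + 1

    lat0 = rng.uniform(*config.latitude_span)
    lon0 = rng.uniform(-170.0, 170.0)
    latitude = np.clip(lat0 + rng.normal(0, 1.5, n), -89.9, 89.9)
    longitude = lon0 + rng.normal(0, 1.5, n)

    local_q = rng.lognormal(config.runoff_log_mean, config.runoff_log_sd, n)
    q_annual = local_q.copy()
    for i in range(n - 1, 0, -1):          # children have larger indices
        q_annual[downstream[i]] += q_annual[i]

    slope = np.exp(rng.normal(np.log(0.02) - 0.5 * (order - 1), 0.6))
    slope = np.clip(slope, 1e-5, 0.3)
    elevation = np.maximum(5.0, 20.0 * depth + rng.lognormal(3.0, 0.5, n))
    length = rng.lognormal(np.log(config.reach_length_log_median_m), 0.5, n)
    q_cv = np.exp(rng.normal(np.log(config.q_cv_mean), 0.3, n))

    df = pd.DataFrame({
        "reach_id": [f"r{i:05d}" for i in range(n)],
        "downstream_id": [f"r{d:05d}" if d >= 0 else "" for d in downstream],
        "length_m": length,
        "slope": slope,
        "elevation_m": elevation,
        "stream_order": order,
        "basin_group": [f"bg{int((la + 90) // 30)}" for la in latitude],
        "latitude": latitude,
        "longitude": longitude,
        "q_cv": q_cv,
    })

    phase = np.where(latitude >= 0, 7.0, 1.0)   # high flow in local summer
    for m in MONTHS:
        season = 1.0 + config.seasonal_amplitude * np.cos(2 * np.pi * (m - phase) / 12.0)
        df[f"q_{m:02d}"] = q_annual * season
        t_air = _air_temperature(latitude, m)
        df[f"tair_{m:02d}"] = t_air
        # ice-free fraction ramps between -5 and +2 degC monthly air temp
        df[f"ice_{m:02d}"] = np.clip((t_air + 5.0) / 7.0, 0.0, 1.0)
    dry_base = np.where(rng.random(n) < 0.2, rng.uniform(0.0, 0.3, n), 0.0)
    for m in MONTHS:
        season = 1.0 + config.seasonal_amplitude * np.cos(2 * np.pi * (m - phase) / 12.0)
        anti = (2.0 - season) / 2.0   # driest in low-flow months
        df[f"dry_{m:02d}"] = np.clip(dry_base * anti, 0.0, 1.0)
    return df


def generate_predictors(reaches: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Per-reach-month predictor table with planted structure.

    Includes the true drivers of the concentration model, a pair of
    near-duplicate columns (``gpp`` tracks ``npp`` with r > 0.95, exercising
    the correlation pruning) and an inert noise column.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(reaches)
    static = pd.DataFrame({
        "reach_id": reaches["reach_id"].to_numpy(),
        "soil_carbon": rng.lognormal(3.0, 0.6, n),
        "wetland_cover": rng.beta(1.5, 6.0, n),
        "human_pop": rng.lognormal(2.0, 1.5, n),
        "slope_log": np.log(reaches["slope"].to_numpy(dtype=float)),
        "elevation_m": reaches["elevation_m"].to_numpy(dtype=float),
    })
    lat = reaches["latitude"].to_numpy(dtype=float)
    frames = []
    for m in MONTHS:
        t_air = reaches[f"tair_{m:02d}"].to_numpy(dtype=float)
        npp = np.maximum(0.0, 1200.0 - 8.0 * np.abs(lat) + 30.0 * t_air
                         + rng.normal(0, 60, n))
        block = static.copy()
        block["month"] = m
        block["t_air"] = t_air
        block["npp"] = npp
        block["gpp"] = npp * 1.8 + rng.normal(0, 10, n)   # near-duplicate
        block["precip"] = np.maximum(
            0.0, 80.0 + 60.0 * np.cos(np.radians(lat)) + rng.normal(0, 20, n))
        block["noise_var"] = rng.normal(0, 1, n)
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def true_log_concentration(predictors: pd.DataFrame, config: SyntheticConfig) -> np.ndarray:
    """Planted ln CH4 concentration (mmol/m^3) for each predictor row.

    Coefficients act on z-scored predictors so their magnitudes are
    comparable; the z-scoring statistics come from the table itself.
    """
    y = np.full(len(predictors), config.conc_intercept_ln)
    for name, beta in config.conc_coeffs.items():
        x = predictors[name].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        y = y + beta * z
    return y


def generate_observations(reaches: pd.DataFrame, predictors: pd.DataFrame,
                          config: SyntheticConfig) -> pd.DataFrame:
    """Site-visit observation table drawn from the planted truth.

    Sites sit on reach midpoints (jittered within ``site_jitter_m``), are
    revisited across months and years, and carry concentration, diffusive
    and ebullitive fluxes, measured k600 with a method label, water
    temperature and a site category. Diffusive flux is Fick's law evaluated
    at the site's reference state, modulated by the Boltzmann factor
    exp(E_M * x(T)) at the true activation energy, so the planted thermal
    slope is exactly ``true_e_m``; ebullition follows the planted ln-ln
    relation on diffusive flux.
    """
    rng = np.random.default_rng(config.seed + 2)
    constants = DEFAULT_CONSTANTS
    eff_revisits = ((1.0 - config.time_series_frac) * config.mean_revisits
                    + config.time_series_frac * config.time_series_revisits)
    n_sites = max(1, int(round(config.n_observations / eff_revisits)))
    site_reach_idx = rng.integers(0, len(reaches), n_sites)
    categories = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in categories], dtype=float)
    probs = probs / probs.sum()
    site_category = rng.choice(categories, n_sites, p=probs)

    truth_ln = true_log_concentration(predictors, config)
    truth = predictors[["reach_id", "month"]].copy()
    truth["ln_c"] = truth_ln
    truth_map = truth.set_index(["reach_id", "month"])["ln_c"]
    truth_annual = truth.groupby("reach_id")["ln_c"].mean()

    # per-site visit counts: mostly short records, a few long time series
    long_record = rng.random(n_sites) < config.time_series_frac
    lam = np.where(long_record, config.time_series_revisits, config.mean_revisits)
    visits = 1 + rng.poisson(np.maximum(lam - 1.0, 0.0))
    extras = np.repeat(np.arange(n_sites), visits - 1)
    rng.shuffle(extras)
    n_extra = max(0, config.n_observations - n_sites)
    if len(extras) < n_extra:   # revisit pool short of target: top up pro rata
        pad = rng.choice(n_sites, n_extra - len(extras), p=lam / lam.sum())
        extras = np.concatenate([extras, pad])
    obs_site = np.concatenate([np.arange(n_sites), extras[:n_extra]])
    rows = []
    lat_r = reaches["latitude"].to_numpy(dtype=float)
    lon_r = reaches["longitude"].to_numpy(dtype=float)
    slope_r = reaches["slope"].to_numpy(dtype=float)
    elev_r = reaches["elevation_m"].to_numpy(dtype=float)
    q_ann = reaches[[f"q_{m:02d}" for m in MONTHS]].mean(axis=1).to_numpy(dtype=float)
    # reference (annual-state) hydraulics for the site base flux
    from .hydrology import DEFAULT_COEFFS
    v_ref = np.where(q_ann > 0, DEFAULT_COEFFS.a_v * q_ann**DEFAULT_COEFFS.b_v, 0.0)

    jitter_deg = config.site_jitter_m / 111_320.0
    site_lat = lat_r[site_reach_idx] + rng.uniform(-jitter_deg, jitter_deg, n_sites)
    site_lon = lon_r[site_reach_idx] + rng.uniform(-jitter_deg, jitter_deg, n_sites) \
        / np.maximum(0.1, np.cos(np.radians(lat_r[site_reach_idx])))

    k_methods = np.array(["chamber", "tracer", "hydraulic_model", "other", "not determined"])
    k_method_p = np.array([0.45, 0.2, 0.2, 0.1, 0.05])

    for j, s in enumerate(obs_site):
        ridx = site_reach_idx[s]
        reach_id = reaches["reach_id"].iat[ridx]
        month = int(rng.integers(1, 13))
        year = int(rng.integers(2010, 2021))
        t_air = _air_temperature(lat_r[ridx], month)
        t_water = float(gas.water_temp_from_air(t_air)) + rng.normal(0, 0.5)
        t_water = min(max(t_water, 0.0), 39.5)
        ln_c = truth_map.loc[(reach_id, month)] + rng.normal(0, config.conc_noise_sd)
        c = float(np.exp(ln_c)) * CATEGORY_MULTIPLIERS.get(site_category[s], 1.0)

        k600_true = gas.k600_from_hydraulics(slope_r[ridx], v_ref[ridx], constants)
        k600_meas = float(k600_true) * float(np.exp(rng.normal(0, 0.2)))
        sc = float(gas.schmidt_ch4(t_water, constants))
        k_ch4_ref = float(gas.k_ch4_from_k600(k600_true, 600.0))
        c_eq_ref = float(gas.equilibrium_concentration(constants.t_ref_c,
                                                       elev_r[ridx], constants))
        # site base flux: Fick's law at the site's reference (annual) state;
        # temperature then enters only through the Boltzmann factor, so the
        # planted within-site thermal slope is exactly true_e_m
        c_ref = float(np.exp(truth_annual.loc[reach_id])) \
            * CATEGORY_MULTIPLIERS.get(site_category[s], 1.0)
        base = max(k_ch4_ref * (c_ref - c_eq_ref), 1e-4)
        x = standardized_temperature_scalar(t_water, constants.t_ref_c)
        flux_diff = base * np.exp(config.true_e_m * x) \
            * np.exp(rng.normal(0, config.flux_noise_sd))
        flux_eb = np.exp(config.ebullition_intercept
                         + config.ebullition_slope * np.log(flux_diff)
                         + rng.normal(0, config.ebullition_noise_sd))
        has_flux = rng.random() < 0.7
        has_eb = has_flux and rng.random() < 0.3
        rows.append({
            "site_id": f"s{s:05d}",
            "study_id": f"study{s // 5:04d}",
            "latitude": site_lat[s],
            "longitude": site_lon[s],
            "date": f"{year}-{month:02d}-15",
            "c_ch4": c,
            "flux_diff": flux_diff if has_flux else np.nan,
            "flux_eb": flux_eb if has_eb else np.nan,
            "k600_measured": k600_meas if has_flux else np.nan,
            "k_method": rng.choice(k_methods, p=k_method_p) if has_flux else "",
            "t_water": t_water,
            "site_category": site_category[s],
            "_sc_ch4": sc,
        })
    return pd.DataFrame(rows).drop(columns=["_sc_ch4"])


def standardized_temperature_scalar(t_water_c: float, t_ref_c: float = 15.0) -> float:
    tk = t_water_c + 273.15
    tr = t_ref_c + 273.15
    return 1.0 / (BOLTZMANN_EV * tr) - 1.0 / (BOLTZMANN_EV * tk)


def generate_arrhenius_fluxes(n: int, e_m: float, noise_sd: float, seed: int,
                              n_sites: int = 1, t_range=(0.0, 30.0)) -> pd.DataFrame:
    """Boltzmann-Arrhenius flux draws for activation-energy recovery tests.

    ln F = ln F0(site) + E_M * x(T) + N(0, noise_sd), with temperatures
    uniform over ``t_range``. Returns columns site_id, t_water, flux_diff.
    """
    rng = np.random.default_rng(seed)
    site = rng.integers(0, n_sites, n)
    ln_f0 = rng.normal(-1.0, 1.0, n_sites)
    t = rng.uniform(t_range[0], t_range[1], n)
    x = np.array([standardized_temperature_scalar(tt) for tt in t])
    ln_f = ln_f0[site] + e_m * x + rng.normal(0, noise_sd, n)
    return pd.DataFrame({
        "site_id": [f"s{i:04d}" for i in site],
        "t_water": t,
        "flux_diff": np.exp(ln_f),
    })


def generate_study(config: SyntheticConfig) -> dict:
    """Generate all three tables plus the ground-truth record."""
    reaches = generate_network(config)
    predictors = generate_predictors(reaches, config)
    observations = generate_observations(reaches, predictors, config)
    return {
        "reaches": reaches,
        "predictors": predictors,
        "observations": observations,
        "ground_truth": config.ground_truth(),
    }
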