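"""Monte Carlo propagation of the three main flux uncertainties and
one-at-a-time sensitivity analysis.

The uncertain inputs are (i) the two coefficients of the gas-transfer model
(published s.d. 107 and 0.209), drawn once per iteration and shared across
reaches because they are global model parameters; (ii) the modelled CH4
concentration, drawn per reach-month from its prediction s.d.; and (iii)
river surface area, perturbed per reach by a width multiplier whose s.d. is
the reach's discharge CV (width scales with discharge, so the two CVs are
taken as equal). Negative draws of concentration, width multiplier or k600
are clipped to zero, which keeps every draw physical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gas
from .constants import DAYS_PER_MONTH, DEFAULT_CONSTANTS, PhysicalConstants
from .fluxes import correct_cap_k, correct_supply_limited
from .hydrology import DEFAULT_COEFFS, HydraulicCoefficients, hydraulic_geometry

__all__ = ["MonteCarloResult", "monte_carlo_totals", "oat_sensitivity"]


@dataclass
class MonteCarloResult:
    """Distribution of global totals over Monte Carlo iterations."""

    n_iter: int
    point_estimate_tg: float
    total_draws_tg: np.ndarray
    percentiles: dict = field(default_factory=dict)
    by_month: pd.DataFrame | None = None
    by_band: pd.DataFrame | None = None

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.total_draws_tg, q))

    def summary(self) -> str:
        p = self.percentiles
        lines = [f"Monte Carlo totals, {self.n_iter} iterations",
                 f"  point estimate : {self.point_estimate_tg:.4g} Tg CH4/yr",
                 f"  mean of draws  : {self.total_draws_tg.mean():.4g} Tg CH4/yr"]
        for name, value in sorted(p.items(), key=lambda kv: float(kv[0])):
            lines.append(f"  p{name:>5}        : {value:.4g} Tg CH4/yr")
        return "\n".join(lines)


def _assemble(reaches: pd.DataFrame, concentrations: pd.DataFrame,
              constants: PhysicalConstants, coeffs: HydraulicCoefficients,
              air_water=(1.0, 0.0)) -> pd.DataFrame:
    """Deterministic per-reach-month state shared by all draws."""
    hyd = hydraulic_geometry(reaches, coeffs)
    static = ["reach_id", "slope", "elevation_m", "latitude", "length_m", "q_cv"]
    t = hyd.merge(reaches[static], on="reach_id")
    tair = reaches[["reach_id"] + [f"tair_{m:02d}" for m in range(1, 13)]].melt(
        id_vars="reach_id", var_name="_m", value_name="t_air")
    tair["month"] = tair["_m"].str.slice(5).astype(int)
    t = t.merge(tair[["reach_id", "month", "t_air"]], on=["reach_id", "month"])
    t["t_water"] = gas.water_temp_from_air(t["t_air"], *air_water)
    t["sc_ch4"] = gas.schmidt_ch4(t["t_water"], constants)
    t["c_eq"] = gas.equilibrium_concentration(t["t_water"], t["elevation_m"], constants)
    cols = ["reach_id", "month", "c_hat"] + (["c_sd"] if "c_sd" in concentrations else [])
    t = t.merge(concentrations[cols], on=["reach_id", "month"], how="left")
    if t["c_hat"].isna().any():
        raise ValueError("concentration field does not cover all reach-months")
    if "c_sd" not in t:
        t["c_sd"] = 0.0
    t["days"] = t["month"].map(lambda m: DAYS_PER_MONTH[m - 1])
    return t


def _total_tg(state: pd.DataFrame, k600_coefs, conc, area_mult,
              correction: str, k_cap: float, constants: PhysicalConstants) -> tuple:
    """Global and per-month totals (Tg/yr) for one parameter draw."""
    a, b = k600_coefs
    k600 = np.maximum(state["_slope_v"].to_numpy() * a + b, 0.0)
    k_ch4 = gas.k_ch4_from_k600(k600, state["sc_ch4"].to_numpy())
    if correction == "cap_k":
        k_used = correct_cap_k(k_ch4, cap=k_cap)
    elif correction == "supply_limited":
        k_used = correct_supply_limited(k_ch4, state["v_ms"].to_numpy(),
                                        state["d_m"].to_numpy(),
                                        state["length_m"].to_numpy())
    else:
        k_used = k_ch4
    rate = k_used * (conc - state["c_eq"].to_numpy())
    emission_g = (rate * state["effective_area_m2"].to_numpy() * area_mult
                  * state["days"].to_numpy() * constants.molar_mass_ch4 * 1e-3)
    month = state["month"].to_numpy()
    by_month = np.bincount(month - 1, weights=emission_g, minlength=12) * 1e-12
    return float(emission_g.sum() * 1e-12), by_month


def monte_carlo_totals(reaches: pd.DataFrame, concentrations: pd.DataFrame,
                       n: int = 1000, seed: int = 0,
                       correction: str = "supply_limited", k_cap: float = 35.0,
                       constants: PhysicalConstants = DEFAULT_CONSTANTS,
                       coeffs: HydraulicCoefficients = DEFAULT_COEFFS,
                       percentiles=(5, 95, 10, 90),
                       air_water=(1.0, 0.0)) -> MonteCarloResult:
    """Monte Carlo distribution of the global emission total.

    Per iteration the k600 coefficients are drawn from their published
    normal uncertainties (shared across reaches), concentrations from
    N(c_hat, c_sd) per reach-month, and a per-reach width multiplier from
    N(1, q_cv); all draws are clipped at zero and the active flux correction
    is re-applied to each draw.
    """
    if n < 2:
        raise ValueError("need at least two Monte Carlo iterations")
    rng = np.random.default_rng(seed)
    state = _assemble(reaches, concentrations, constants, coeffs, air_water)
    state["_slope_v"] = state["slope"].to_numpy() * state["v_ms"].to_numpy()
    reach_codes, reach_idx = np.unique(state["reach_id"].to_numpy(), return_inverse=True)

    point, point_by_month = _total_tg(
        state, (constants.k600_slope, constants.k600_intercept),
        state["c_hat"].to_numpy(), 1.0, correction, k_cap, constants)

    draws = np.empty(n)
    month_draws = np.empty((n, 12))
    c_hat = state["c_hat"].to_numpy()
    c_sd = state["c_sd"].to_numpy()
    q_cv_by_reach = state.groupby("reach_id")["q_cv"].first().loc[reach_codes].to_numpy()
    for i in range(n):
        a = rng.normal(constants.k600_slope, constants.k600_slope_sd)
        b = rng.normal(constants.k600_intercept, constants.k600_intercept_sd)
        conc = np.maximum(rng.normal(c_hat, c_sd), 0.0)
        mult_reach = np.maximum(rng.normal(1.0, q_cv_by_reach), 0.0)
        draws[i], month_draws[i] = _total_tg(
            state, (a, b), conc, mult_reach[reach_idx], correction, k_cap, constants)

    pct = {str(q): float(np.percentile(draws, q)) for q in percentiles}
    by_month = pd.DataFrame({
        "month": np.arange(1, 13),
        "point_tg": point_by_month,
        **{f"p{q}": np.percentile(month_draws, q, axis=0) for q in percentiles},
    })
    return MonteCarloResult(n_iter=n, point_estimate_tg=point,
                            total_draws_tg=draws, percentiles=pct, by_month=by_month)


def oat_sensitivity(reaches: pd.DataFrame, concentrations: pd.DataFrame,
                    correction: str = "supply_limited", k_cap: float = 35.0,
                    constants: PhysicalConstants = DEFAULT_CONSTANTS,
                    coeffs: HydraulicCoefficients = DEFAULT_COEFFS,
                    air_water=(1.0, 0.0)) -> pd.DataFrame:
    """One-at-a-time sensitivity: shift each uncertain parameter by +-1 s.d.

    Six deterministic runs (three parameters x two directions), others held
    at their means. Returns totals and deltas relative to the baseline.
    """
    state = _assemble(reaches, concentrations, constants, coeffs, air_water)
    state["_slope_v"] = state["slope"].to_numpy() * state["v_ms"].to_numpy()
    c_hat = state["c_hat"].to_numpy()
    c_sd = state["c_sd"].to_numpy()
    q_cv = state["q_cv"].to_numpy()
    base_coefs = (constants.k600_slope, constants.k600_intercept)
    baseline, _ = _total_tg(state, base_coefs, c_hat, 1.0, correction, k_cap, constants)

    rows = []
    for direction in (+1, -1):
        coefs = (constants.k600_slope + direction * constants.k600_slope_sd,
                 constants.k600_intercept + direction * constants.k600_intercept_sd)
        total, _ = _total_tg(state, coefs, c_hat, 1.0, correction, k_cap, constants)
        rows.append(("k600", direction, total))
        conc = np.maximum(c_hat + direction * c_sd, 0.0)
        total, _ = _total_tg(state, base_coefs, conc, 1.0, correction, k_cap, constants)
        rows.append(("concentration", direction, total))
        mult = np.maximum(1.0 + direction * q_cv, 0.0)
        total, _ = _total_tg(state, base_coefs, c_hat, mult, correction, k_cap, constants)
        rows.append(("area", direction, total))
    out = pd.DataFrame(rows, columns=["parameter", "direction", "total_tg"])
    out["baseline_tg"] = baseline
    out["delta_tg"] = out["total_tg"] - baseline
    return out
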