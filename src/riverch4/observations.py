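"""Observation ingestion: category filtering, site-to-reach snapping,
reach-month aggregation, monthly modelling windows and predictor pruning.

The observation table mirrors the column semantics of a global river methane
database: one row per site visit with coordinates, date, dissolved CH4
concentration (mmol/m^3), optional diffusive/ebullitive fluxes
(mmol m^-2 d^-1), optional measured k600 and its method label, water
temperature and a site-category label. "Targeted" categories (below
wastewater treatment plants, fracking-affected, below dams) and habitats
absent from the hydrography (ditches, glacial termini, canals, thaw slumps)
carry CH4 signals that catchment predictors cannot represent and are
excluded before modelling.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

#: Site categories excluded from concentration modelling by default.
DEFAULT_EXCLUDED_CATEGORIES = (
    "fracking", "below_dam", "below_wwtp", "ditch", "glacial_terminus",
    "canal", "thaw_slump",
)


def filter_observations(observations: pd.DataFrame,
                        excluded_categories=DEFAULT_EXCLUDED_CATEGORIES,
                        known_categories=None) -> tuple[pd.DataFrame, dict]:
    """Drop observations whose site category is in ``excluded_categories``.

    Returns the retained table and an exclusion report with per-category
    counts. Labels outside ``known_categories`` (when given) trigger a
    warning but are retained, so an unrecognised vocabulary never silently
    deletes data.
    """
    cats = observations["site_category"].astype(str)
    if known_categories is not None:
        unknown = sorted(set(cats) - set(known_categories) - set(excluded_categories))
        if unknown:
            warnings.warn(f"unknown site categories retained: {unknown}")
    mask = cats.isin(excluded_categories)
    report = {
        "n_input": int(len(observations)),
        "n_retained": int((~mask).sum()),
        "n_excluded": int(mask.sum()),
        "excluded_by_category": {
            k: int(v) for k, v in cats[mask].value_counts().items()},
    }
    return observations.loc[~mask].copy(), report


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between coordinate arrays (degrees)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h))


def snap_sites(observations: pd.DataFrame, reaches: pd.DataFrame,
               max_dist_m: float = 500.0) -> pd.DataFrame:
    """Map each site to the nearest reach midpoint by great-circle distance.

    Reaches must carry ``latitude``/``longitude`` midpoint coordinates.
    Sites farther than ``max_dist_m`` from any reach are flagged unmapped
    (``mapped=False``) but keep their nearest reach and distance for
    reporting. Returns one row per unique site.
    """
    if len(reaches) == 0:
        raise ValueError("cannot snap sites: reach table is empty")
    sites = observations.drop_duplicates("site_id")[["site_id", "latitude", "longitude"]]
    if len(sites) == 0:
        return pd.DataFrame(columns=["site_id", "reach_id", "dist_m", "mapped"])
    from sklearn.neighbors import BallTree

    tree = BallTree(np.radians(reaches[["latitude", "longitude"]].to_numpy(dtype=float)),
                    metric="haversine")
    dist, idx = tree.query(np.radians(sites[["latitude", "longitude"]].to_numpy(dtype=float)), k=1)
    dist_m = dist[:, 0] * EARTH_RADIUS_M
    out = pd.DataFrame({
        "site_id": sites["site_id"].to_numpy(),
        "reach_id": reaches["reach_id"].to_numpy()[idx[:, 0]],
        "dist_m": dist_m,
        "mapped": dist_m <= max_dist_m,
    })
    n_un = int((~out["mapped"]).sum())
    if n_un:
        log.info("%d of %d sites beyond %.0f m of any reach", n_un, len(out), max_dist_m)
    return out


def aggregate_to_reach_month(observations: pd.DataFrame, mapping: pd.DataFrame,
                             value_col: str = "c_ch4",
                             across_years: str = "mean",
                             across_sites: str = "mean") -> pd.DataFrame:
    """Two-stage aggregation of observations to one value per reach-month.

    Stage 1 collapses repeat visits across years within each site-month;
    stage 2 collapses sites within each reach-month. Each stage uses mean or
    median (config switch; the source analysis describes both and they
    coincide for symmetric data). Only mapped sites contribute.
    """
    if across_years not in ("mean", "median") or across_sites not in ("mean", "median"):
        raise ValueError("aggregation statistics must be 'mean' or 'median'")
    obs = observations.merge(mapping.loc[mapping["mapped"], ["site_id", "reach_id"]],
                             on="site_id", how="inner")
    obs = obs[obs[value_col].notna()].copy()
    obs["month"] = pd.to_datetime(obs["date"]).dt.month
    site_month = obs.groupby(["reach_id", "site_id", "month"], as_index=False)[value_col] \
        .agg(across_years)
    reach_month = site_month.groupby(["reach_id", "month"], as_index=False)[value_col] \
        .agg(across_sites)
    return reach_month.sort_values(["reach_id", "month"]).reset_index(drop=True)


def build_monthly_window(dataset: pd.DataFrame, month: int,
                         test_fraction: float = 0.2, seed: int = 0,
                         month_col: str = "month") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Training window for one monthly model: the month plus its neighbours.

    Rows whose month lies in {m-1, m, m+1} (December/January wrap around)
    are pooled to stabilise months with sparse coverage, then split 80/20
    into train/test with a fixed seed.
    """
    if not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")
    window = {(month - 2) % 12 + 1, month, month % 12 + 1}
    rows = dataset[dataset[month_col].isin(window)]
    if len(rows) == 0:
        raise ValueError(f"no observations in the window around month {month}")
    from sklearn.model_selection import train_test_split

    if len(rows) < 2:
        return rows.copy(), rows.iloc[0:0].copy()
    train, test = train_test_split(rows, test_size=test_fraction, random_state=seed)
    return train, test


def prune_predictors(dataset: pd.DataFrame, predictor_cols,
                     r_max: float = 0.95, keep_priority=(),
                     skew_threshold: float = 2.0,
                     log_offset: float | None = None) -> tuple[pd.DataFrame, dict]:
    """Drop near-duplicate predictors and log-transform heavily skewed ones.

    Constant columns are dropped with a warning. For every pair with
    |Pearson r| > ``r_max`` the member earlier in ``keep_priority`` wins;
    ties fall to the column listed first in ``predictor_cols``. Remaining
    columns with |skewness| above ``skew_threshold`` are transformed to
    ``log(x + offset)`` where the offset defaults to half the smallest
    positive value (0 for all-positive columns). Returns the transformed
    dataset and a decision log.
    """
    cols = list(predictor_cols)
    report: dict = {"dropped_constant": [], "dropped_correlated": [], "log_transformed": {}}
    data = dataset.copy()

    for c in list(cols):
        if data[c].nunique(dropna=True) <= 1:
            cols.remove(c)
            report["dropped_constant"].append(c)
    if report["dropped_constant"]:
        warnings.warn(f"dropped constant predictors: {report['dropped_constant']}")

    priority = {name: i for i, name in enumerate(keep_priority)}

    def rank(c):  # lower is better
        return (priority.get(c, len(priority)), cols.index(c))

    corr = data[cols].corr().abs()
    dropped = set()
    for i, a in enumerate(cols):
        if a in dropped:
            continue
        for b in cols[i + 1:]:
            if b in dropped or corr.loc[a, b] <= r_max:
                continue
            loser = b if rank(a) <= rank(b) else a
            dropped.add(loser)
            report["dropped_correlated"].append(
                {"kept": a if loser == b else b, "dropped": loser,
                 "r": float(corr.loc[a, b])})
            if loser == a:
                break
    kept = [c for c in cols if c not in dropped]

    for c in kept:
        x = data[c].to_numpy(dtype=float)
        if abs(stats.skew(x, nan_policy="omit")) > skew_threshold:
            pos = x[x > 0]
            if log_offset is not None:
                off = log_offset
            else:
                off = 0.0 if (x > 0).all() else (pos.min() / 2.0 if pos.size else 1.0)
            data[c] = np.log(x + off)
            report["log_transformed"][c] = float(off)

    data = data.drop(columns=[c for c in predictor_cols if c not in kept])
    report["kept"] = kept
    return data, report
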