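"""End-to-end orchestration: observations to global emission totals.

:class:`RiverMethaneModel` ties the stages together in dependency order —
observation filtering, site snapping, reach-month aggregation, predictor
pruning, monthly concentration models, diffusive upscaling with the
supply-limitation correction, Monte Carlo uncertainty, ebullition scaling
and the thermal analysis — and :class:`RiverMethaneResults` carries the
fitted pieces with a ``summary()``. Each run can be written to disk with a
manifest recording the config hash, seeds and input digests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .concentration import ConcentrationModel, RegressorConfig
from .constants import DEFAULT_CONSTANTS
from .ebullition import EbullitionModel, pair_and_filter, upscale_ebullition
from .fluxes import upscale, validate_against_measured
from .hydrology import DEFAULT_COEFFS
from .observations import (DEFAULT_EXCLUDED_CATEGORIES, aggregate_to_reach_month,
                           filter_observations, prune_predictors, snap_sites)
from .synthetic import SyntheticConfig, generate_study
from .thermal import compare_em_distributions, site_activation_energies
from .uncertainty import monte_carlo_totals, oat_sensitivity

PREDICTOR_COLS = ("soil_carbon", "wetland_cover", "npp", "gpp", "precip",
                  "t_air", "human_pop", "slope_log", "elevation_m", "noise_var")


class PipelineConfig(BaseModel):
    """Single config for a full run; every stage threshold lives here."""

    model_config = ConfigDict(extra="forbid")

    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    predictor_cols: tuple[str, ...] = PREDICTOR_COLS
    excluded_categories: tuple[str, ...] = DEFAULT_EXCLUDED_CATEGORIES
    snap_dist_m: float = 500.0
    r_max: float = 0.95
    keep_priority: tuple[str, ...] = ("npp", "soil_carbon")
    n_trees: int = 300
    mtry: int = 13
    min_n: int = 8
    correction: str = "supply_limited"
    k_cap_m_per_day: float = 35.0
    mc_n: int = 1000
    min_site_obs: int = 20
    seed: int = 1


def apply_transforms(predictors: pd.DataFrame, prune_report: dict) -> pd.DataFrame:
    """Apply the pruning stage's log transforms to a prediction table."""
    out = predictors.copy()
    for col, offset in prune_report.get("log_transformed", {}).items():
        out[col] = np.log(out[col].to_numpy(dtype=float) + offset)
    return out


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    input_digests: dict
    version: str = __version__
    created: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


class RiverMethaneModel:
    """Riverine CH4 emission model built from a reach network, an
    observation table and a per-reach-month predictor table."""

    def __init__(self, reaches: pd.DataFrame, observations: pd.DataFrame,
                 predictors: pd.DataFrame, config: PipelineConfig | None = None):
        self.reaches = reaches
        self.observations = observations
        self.predictors = predictors
        self.config = config or PipelineConfig()

    @classmethod
    def from_synthetic(cls, config: PipelineConfig | None = None) -> "RiverMethaneModel":
        config = config or PipelineConfig()
        study = generate_study(config.synthetic)
        model = cls(study["reaches"], study["observations"], study["predictors"], config)
        model.ground_truth = study["ground_truth"]
        return model

    def fit(self) -> "RiverMethaneResults":
        cfg = self.config
        retained, exclusion_report = filter_observations(
            self.observations, cfg.excluded_categories)
        mapping = snap_sites(retained, self.reaches, max_dist_m=cfg.snap_dist_m)
        response = aggregate_to_reach_month(retained, mapping)

        dataset = response.merge(self.predictors, on=["reach_id", "month"], how="inner")
        cols = [c for c in cfg.predictor_cols if c in dataset.columns]
        dataset, prune_report = prune_predictors(
            dataset, cols, r_max=cfg.r_max, keep_priority=cfg.keep_priority)
        kept = prune_report["kept"]

        conc_model = ConcentrationModel(
            dataset, kept, response_col="c_ch4",
            regressor=RegressorConfig(n_trees=cfg.n_trees, mtry=cfg.mtry,
                                      min_n=cfg.min_n, seed=cfg.seed),
            split_seed=cfg.seed)
        conc_results = conc_model.fit()

        prediction_table = apply_transforms(self.predictors, prune_report)
        field_df = conc_results.predict(prediction_table)

        fluxes, totals = upscale(self.reaches, field_df, correction=cfg.correction,
                                 k_cap=cfg.k_cap_m_per_day)
        return RiverMethaneResults(
            model=self, mapping=mapping, exclusion_report=exclusion_report,
            prune_report=prune_report, concentration=conc_results,
            concentration_field=field_df, fluxes=fluxes, totals=totals)


class RiverMethaneResults:
    """Fitted pipeline state: concentration field, fluxes, diagnostics."""

    def __init__(self, model, mapping, exclusion_report, prune_report,
                 concentration, concentration_field, fluxes, totals):
        self.model = model
        self.mapping = mapping
        self.exclusion_report = exclusion_report
        self.prune_report = prune_report
        self.concentration = concentration
        self.concentration_field = concentration_field
        self.fluxes = fluxes
        self.totals = totals

    # -- downstream analyses -----------------------------------------------
    def monte_carlo(self, n: int | None = None, seed: int | None = None):
        cfg = self.model.config
        return monte_carlo_totals(
            self.model.reaches, self.concentration_field,
            n=n or cfg.mc_n, seed=cfg.seed if seed is None else seed,
            correction=cfg.correction, k_cap=cfg.k_cap_m_per_day,
            percentiles=(2.5, 5, 10, 90, 95, 97.5))

    def sensitivity(self):
        cfg = self.model.config
        return oat_sensitivity(self.model.reaches, self.concentration_field,
                               correction=cfg.correction, k_cap=cfg.k_cap_m_per_day)

    def ebullition(self, mc_result=None) -> dict:
        pairs, report = pair_and_filter(self.model.observations)
        eb = EbullitionModel(pairs).fit()
        out = {"fit": eb, "report": report}
        if mc_result is not None:
            out["total"] = upscale_ebullition(
                eb, mc_result.point_estimate_tg,
                diffusive_p025_tg=mc_result.percentile(2.5),
                diffusive_p975_tg=mc_result.percentile(97.5))
        return out

    def thermal(self, reference_em=None) -> dict:
        fits, info = site_activation_energies(
            self.model.observations, min_n=self.model.config.min_site_obs)
        out = {"fits": fits, "info": info}
        sites = fits[fits["site_id"] != "pooled"]
        if reference_em is not None and len(sites) >= 2:
            out["comparison"] = compare_em_distributions(
                sites["e_m"].to_numpy(), reference_em)
        return out

    def validation(self, **kwargs) -> dict:
        return validate_against_measured(self.fluxes, self.model.observations,
                                         self.model.reaches, **kwargs)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        t = self.totals
        lines = [
            "Riverine CH4 emission pipeline",
            f"  reaches            : {len(self.model.reaches)}",
            f"  observations       : {self.exclusion_report['n_input']} "
            f"({self.exclusion_report['n_retained']} retained after category filter)",
            f"  predictors kept    : {len(self.prune_report['kept'])}"
            f" of {len(self.model.config.predictor_cols)}",
            f"  correction         : {self.model.config.correction}",
            f"  global diffusive   : {t['global_tg_per_yr']:.4g} Tg CH4/yr",
        ]
        return "\n".join(lines)

    def manifest(self) -> RunManifest:
        cfg_json = self.model.config.model_dump_json()
        return RunManifest(
            config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
            seeds={"pipeline": self.model.config.seed,
                   "synthetic": self.model.config.synthetic.seed},
            input_digests={
                "reaches": _digest(self.model.reaches),
                "observations": _digest(self.model.observations),
                "predictors": _digest(self.model.predictors),
            })

    def write(self, outdir) -> None:
        """Write flux table, concentration field, totals and manifest."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.fluxes.to_csv(out / "fluxes.csv", index=False)
        self.concentration_field.to_csv(out / "concentration_field.csv", index=False)
        (out / "totals.json").write_text(json.dumps(self.totals, indent=2))
        (out / "manifest.json").write_text(self.manifest().to_json())


def run_pipeline(config: PipelineConfig | None = None, outdir=None) -> RiverMethaneResults:
    """Run the full pipeline on a synthetic study and optionally persist it."""
    model = RiverMethaneModel.from_synthetic(config)
    results = model.fit()
    if outdir is not None:
        results.write(outdir)
    return results
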