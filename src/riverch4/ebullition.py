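"""Ebullitive CH4 emissions scaled from the diffusive estimate.

Ebullition (bubble release from sediments) is too sparsely measured for
spatial modelling, but paired observations show diffusive and ebullitive
fluxes are of the same magnitude and linearly related in log space. The
fitted log-log regression, applied to the diffusive global total, gives a
first-order ebullitive total; its uncertainty combines the Monte Carlo
spread of the diffusive estimate with the regression prediction interval by
taking the lower prediction bound at the diffusive 2.5th percentile and the
upper bound at the 97.5th percentile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["pair_and_filter", "EbullitionModel", "EbullitionResults", "upscale_ebullition"]

#: k600-method labels treated as hydraulically modelled (excluded from pairing).
HYDRAULIC_K_METHODS = ("hydraulic_model",)


def pair_and_filter(observations: pd.DataFrame, min_flux: float = 1e-4,
                    excluded_k_methods=HYDRAULIC_K_METHODS) -> tuple[pd.DataFrame, dict]:
    """Select observation rows carrying both diffusive and ebullitive flux.

    Pairs come from the same site and sampling occasion (one table row).
    Fluxes below ``min_flux`` mmol m^-2 d^-1 (negligible or uncertain) and
    observations whose k600 was modelled from hydraulic relationships are
    excluded. Returns the retained pairs and a filter report.
    """
    both = observations[observations["flux_diff"].notna()
                        & observations["flux_eb"].notna()].copy()
    report = {"n_pairs_raw": int(len(both))}
    above = both[(both["flux_diff"] >= min_flux) & (both["flux_eb"] >= min_flux)]
    report["n_below_min_flux"] = int(len(both) - len(above))
    if "k_method" in above.columns:
        kept = above[~above["k_method"].isin(excluded_k_methods)]
    else:
        kept = above
    report["n_hydraulic_k"] = int(len(above) - len(kept))
    report["n_retained"] = int(len(kept))
    if len(kept) == 0:
        raise ValueError("no diffusive-ebullitive flux pairs survive the filters")
    return kept.reset_index(drop=True), report


class EbullitionModel:
    """OLS of log ebullitive flux on log diffusive flux.

    ``log_base`` controls the display convention only; fitting is in
    natural-log space and slope is base-invariant.
    """

    def __init__(self, pairs: pd.DataFrame, diff_col: str = "flux_diff",
                 eb_col: str = "flux_eb"):
        if len(pairs) < 3:
            raise ValueError("need at least three flux pairs to fit")
        self.pairs = pairs
        self.x = np.log(pairs[diff_col].to_numpy(dtype=float))
        self.y = np.log(pairs[eb_col].to_numpy(dtype=float))
        if np.ptp(self.x) == 0:
            raise ValueError("diffusive fluxes are degenerate (zero variance in log space)")

    def fit(self) -> "EbullitionResults":
        import statsmodels.api as sm

        fit = sm.OLS(self.y, sm.add_constant(self.x)).fit()
        return EbullitionResults(self, fit)


class EbullitionResults:
    """Fitted log-log relation with prediction intervals."""

    def __init__(self, model: EbullitionModel, fit):
        self.model = model
        self._fit = fit
        self.intercept = float(fit.params[0])
        self.slope = float(fit.params[1])
        self.slope_se = float(fit.bse[1])
        self.residual_sd = float(np.sqrt(fit.mse_resid))
        self.n_pairs = int(fit.nobs)

    def conf_int_slope(self, alpha: float = 0.05) -> tuple[float, float]:
        lo, hi = self._fit.conf_int(alpha=alpha)[1]
        return float(lo), float(hi)

    def predict_ln(self, ln_diff) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(ln_diff, dtype=float)

    def prediction_interval(self, ln_diff, level: float = 0.95) -> pd.DataFrame:
        """Prediction interval for a new observation, natural-log space.

        At level 0 the interval collapses onto the regression line; it
        widens away from the mean of the fitted diffusive fluxes.
        """
        import statsmodels.api as sm

        ln_diff = np.atleast_1d(np.asarray(ln_diff, dtype=float))
        X = sm.add_constant(ln_diff, has_constant="add")
        pred = self._fit.get_prediction(X)
        frame = pred.summary_frame(alpha=1.0 - level)
        return pd.DataFrame({"ln_diff": ln_diff, "mean": frame["mean"].to_numpy(),
                             "lower": frame["obs_ci_lower"].to_numpy(),
                             "upper": frame["obs_ci_upper"].to_numpy()})

    def summary(self) -> str:
        lo, hi = self.conf_int_slope()
        return ("Ebullition ~ diffusion (natural log space)\n"
                f"  slope        : {self.slope:.4f} (se {self.slope_se:.4f}, "
                f"95% CI [{lo:.4f}, {hi:.4f}])\n"
                f"  intercept    : {self.intercept:.4f}\n"
                f"  residual s.d.: {self.residual_sd:.4f}\n"
                f"  n pairs      : {self.n_pairs}")


def upscale_ebullition(results: EbullitionResults, diffusive_total_tg: float,
                       diffusive_p025_tg: float | None = None,
                       diffusive_p975_tg: float | None = None,
                       level: float = 0.95) -> dict:
    """Ebullitive total (Tg CH4/yr) from the diffusive total.

    The regression is applied in log space to the total itself. The bounds
    take the lower prediction-interval bound evaluated at the diffusive
    2.5th percentile and the upper bound at the 97.5th percentile, so both
    sources of uncertainty (Monte Carlo and regression scatter) widen the
    interval.
    """
    if diffusive_total_tg <= 0:
        raise ValueError("diffusive total must be positive")
    central = float(np.exp(results.predict_ln(np.log(diffusive_total_tg))))
    out = {"central_tg": central}
    if diffusive_p025_tg is not None and diffusive_p975_tg is not None:
        lo = results.prediction_interval(np.log(diffusive_p025_tg), level)
        hi = results.prediction_interval(np.log(diffusive_p975_tg), level)
        out["lower_tg"] = float(np.exp(lo["lower"].iloc[0]))
        out["upper_tg"] = float(np.exp(hi["upper"].iloc[0]))
    return out
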