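"""Monthly predictive models of reach CH4 concentration.

Twelve regressors are fitted, one per calendar month, each trained on the
month plus its two neighbours (80/20 train/test split). The response is
modelled in log space. The backend is pluggable through
:class:`RegressorConfig`; the default is a random forest with the pinned
hyperparameters mtry = 13, min_n = 8, n_trees = 1200. Per-prediction
standard deviations of the ensemble mean come from the bias-corrected
infinitesimal-jackknife estimator (Wager, Hastie & Efron 2014) computed from
the forest's bootstrap membership, with a bootstrap-member-spread fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observations import build_monthly_window

__all__ = ["RegressorConfig", "ConcentrationModel", "ConcentrationResults",
           "flag_extrapolation", "infinitesimal_jackknife_sd"]


@dataclass
class RegressorConfig:
    """Backend choice and hyperparameters for the monthly models.

    ``mtry`` is the number of predictors tried per split and ``min_n`` the
    minimum node size before splitting (random-forest conventions).
    """

    backend: str = "random_forest"
    n_trees: int = 1200
    mtry: int = 13
    min_n: int = 8
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def build(self, n_predictors: int):
        if self.backend == "random_forest":
            from sklearn.ensemble import RandomForestRegressor

            return RandomForestRegressor(
                n_estimators=self.n_trees,
                max_features=min(self.mtry, n_predictors),
                min_samples_split=max(2, self.min_n),
                random_state=self.seed,
                bootstrap=True,
                n_jobs=1,
                **self.extra,
            )
        if self.backend == "extra_trees":
            from sklearn.ensemble import ExtraTreesRegressor

            return ExtraTreesRegressor(
                n_estimators=self.n_trees,
                max_features=min(self.mtry, n_predictors),
                min_samples_split=max(2, self.min_n),
                random_state=self.seed, bootstrap=True, n_jobs=1, **self.extra)
        raise ValueError(f"unknown regressor backend {self.backend!r}")


def _inbag_counts(forest, n_samples: int) -> np.ndarray | None:
    """Bootstrap in-bag counts per (tree, training sample), re-derived from
    each tree's random state. Returns None if the backend internals are
    unavailable (triggering the fallback estimator)."""
    try:
        from sklearn.ensemble._forest import _generate_sample_indices

        counts = np.empty((len(forest.estimators_), n_samples))
        for b, est in enumerate(forest.estimators_):
            idx = _generate_sample_indices(est.random_state, n_samples, n_samples)
            counts[b] = np.bincount(idx, minlength=n_samples)
        return counts
    except Exception:  # pragma: no cover - version drift guard
        return None


def infinitesimal_jackknife_sd(forest, n_train: int, X: np.ndarray) -> tuple[np.ndarray, str]:
    """Standard deviation of the forest's mean prediction at each row of X.

    Implements the bias-corrected infinitesimal jackknife for bagged
    ensembles: V(x) = sum_i cov_b(N_bi, t_b(x))^2 - (n/B^2) sum_b
    (t_b(x) - t_bar(x))^2, where N_bi counts appearances of training sample
    i in bootstrap b and t_b are per-tree predictions. Falls back to the
    plain spread of bootstrap-member predictions when in-bag counts cannot
    be recovered. Returns (sd, method_label).
    """
    preds = np.stack([est.predict(X) for est in forest.estimators_])  # (B, m)
    B = preds.shape[0]
    counts = _inbag_counts(forest, n_train)
    centered = preds - preds.mean(axis=0, keepdims=True)
    if counts is None:
        return preds.std(axis=0, ddof=1) / np.sqrt(B), "bootstrap_spread"
    n_c = counts - counts.mean(axis=0, keepdims=True)                 # (B, n)
    cov = n_c.T @ centered / B                                        # (n, m)
    v_ij = (cov**2).sum(axis=0)
    bias = n_train / B**2 * (centered**2).sum(axis=0)
    return np.sqrt(np.maximum(v_ij - bias, 0.0)), "infinitesimal_jackknife"


def flag_extrapolation(train: pd.DataFrame, predict: pd.DataFrame,
                       predictor_cols, quantiles=(0.01, 0.99)) -> np.ndarray:
    """Flag prediction rows with any predictor outside the training
    [q_lo, q_hi] range — a deliberately simple per-predictor stand-in for
    convex-domain extrapolation screening."""
    lo = train[list(predictor_cols)].quantile(quantiles[0])
    hi = train[list(predictor_cols)].quantile(quantiles[1])
    p = predict[list(predictor_cols)]
    return ((p.lt(lo, axis=1)) | (p.gt(hi, axis=1))).any(axis=1).to_numpy()


class ConcentrationModel:
    """Monthly concentration model over an aggregated reach-month dataset.

    Parameters
    ----------
    dataset : DataFrame
        One row per reach-month with the response column, predictor columns
        and a ``month`` column.
    predictor_cols : sequence of str
    response_col : str
        Concentration in mmol/m^3; modelled as ln(response).
    regressor : RegressorConfig, optional
    split_seed : int
        Seed of the 80/20 train/test split in each monthly window.
    """

    def __init__(self, dataset: pd.DataFrame, predictor_cols, response_col="c_ch4",
                 regressor: RegressorConfig | None = None, split_seed: int = 0,
                 log_response: bool = True, bias_correction: bool = False):
        self.dataset = dataset.reset_index(drop=True)
        self.predictor_cols = list(predictor_cols)
        self.response_col = response_col
        self.regressor = regressor or RegressorConfig()
        self.split_seed = split_seed
        self.log_response = log_response
        self.bias_correction = bias_correction
        missing = [c for c in self.predictor_cols + [response_col, "month"]
                   if c not in dataset.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")

    def _response(self, frame: pd.DataFrame) -> np.ndarray:
        y = frame[self.response_col].to_numpy(dtype=float)
        if self.log_response:
            if np.any(y <= 0):
                raise ValueError("log response requires strictly positive concentrations")
            return np.log(y)
        return y

    def fit(self, months=range(1, 13), importance_repeats: int = 5) -> "ConcentrationResults":
        """Fit the monthly models; returns a results object with test-set
        metrics and permutation importances per month."""
        from sklearn.inspection import permutation_importance
        from sklearn.metrics import mean_squared_error, r2_score

        models, trains, reports = {}, {}, []
        for m in months:
            train, test = build_monthly_window(self.dataset, m, seed=self.split_seed)
            if len(train) < 5:
                raise ValueError(f"month {m}: window too small to split ({len(train)} rows)")
            X_tr = train[self.predictor_cols].to_numpy(dtype=float)
            y_tr = self._response(train)
            reg = self.regressor.build(len(self.predictor_cols)).fit(X_tr, y_tr)
            models[m], trains[m] = reg, train
            report = {"month": m, "n_train": len(train), "n_test": len(test)}
            if len(test) >= 2:
                X_te = test[self.predictor_cols].to_numpy(dtype=float)
                y_te = self._response(test)
                pred = reg.predict(X_te)
                report["r2_test"] = float(r2_score(y_te, pred))
                report["rmse_test"] = float(np.sqrt(mean_squared_error(y_te, pred)))
                imp = permutation_importance(
                    reg, X_te, y_te, n_repeats=importance_repeats,
                    random_state=self.split_seed)
                report["importance"] = dict(zip(self.predictor_cols,
                                                imp.importances_mean.tolist()))
            reports.append(report)
        return ConcentrationResults(self, models, trains, reports)


class ConcentrationResults:
    """Fitted monthly models with prediction, uncertainty and diagnostics."""

    def __init__(self, model: ConcentrationModel, models: dict, trains: dict,
                 reports: list[dict]):
        self.model = model
        self.models = models
        self.trains = trains
        self.reports = reports
        self.uncertainty_method: str | None = None

    # -- prediction ---------------------------------------------------------
    def predict(self, predictors: pd.DataFrame, with_uncertainty: bool = True,
                quantiles=(0.01, 0.99)) -> pd.DataFrame:
        """Concentration field for a reach-month predictor table.

        Returns ``reach_id, month, c_hat, c_sd, extrapolation_flag`` with
        ``c_hat`` back-transformed to mmol/m^3 and ``c_sd`` the s.d. of the
        mean prediction mapped to response units by the delta method.
        """
        missing = [c for c in self.model.predictor_cols if c not in predictors.columns]
        if missing:
            raise ValueError(f"prediction table missing predictor columns: {missing}")
        out = []
        for m, reg in self.models.items():
            rows = predictors[predictors["month"] == m]
            if len(rows) == 0:
                continue
            X = rows[self.model.predictor_cols].to_numpy(dtype=float)
            mean_log = reg.predict(X)
            if with_uncertainty and hasattr(reg, "estimators_"):
                sd_log, method = infinitesimal_jackknife_sd(reg, len(self.trains[m]), X)
                self.uncertainty_method = method
            else:
                sd_log = np.zeros(len(rows))
            if self.model.log_response:
                correction = np.exp(0.5 * sd_log**2) if self.model.bias_correction else 1.0
                c_hat = np.exp(mean_log) * correction
                c_sd = c_hat * sd_log          # delta method
            else:
                c_hat, c_sd = mean_log, sd_log
            flag = flag_extrapolation(self.trains[m], rows,
                                      self.model.predictor_cols, quantiles)
            out.append(pd.DataFrame({
                "reach_id": rows["reach_id"].to_numpy(),
                "month": m,
                "c_hat": c_hat,
                "c_sd": c_sd,
                "extrapolation_flag": flag,
            }))
        return pd.concat(out, ignore_index=True)

    # -- diagnostics --------------------------------------------------------
    def importance_summary(self) -> pd.DataFrame:
        """Median and s.d. of permutation importance across monthly models."""
        rows = [r["importance"] for r in self.reports if "importance" in r]
        if not rows:
            raise ValueError("no test-set importances available")
        frame = pd.DataFrame(rows)
        return pd.DataFrame({
            "median_importance": frame.median(),
            "sd_importance": frame.std(),
        }).sort_values("median_importance", ascending=False)

    def partial_dependence(self, variable: str, grid=None, n_grid: int = 20,
                           data: pd.DataFrame | None = None) -> pd.DataFrame:
        """Marginal effect of one predictor on the predicted response.

        The background data default to yearly per-reach averages of the
        training tables (one row per reach), the variable is clamped to
        each grid point and predictions are averaged over rows and monthly
        models. Returns columns ``grid`` and ``response`` (log space).
        """
        if variable not in self.model.predictor_cols:
            raise ValueError(f"unknown predictor {variable!r}")
        if data is None:
            pooled = pd.concat(self.trains.values(), ignore_index=True)
            data = pooled.groupby("reach_id", as_index=False)[self.model.predictor_cols].mean()
        base = data[self.model.predictor_cols].to_numpy(dtype=float)
        j = self.model.predictor_cols.index(variable)
        if grid is None:
            grid = np.quantile(base[:, j], np.linspace(0.05, 0.95, n_grid))
        response = []
        for g in np.asarray(grid, dtype=float):
            X = base.copy()
            X[:, j] = g
            preds = [reg.predict(X).mean() for reg in self.models.values()]
            response.append(float(np.mean(preds)))
        return pd.DataFrame({"grid": np.asarray(grid, dtype=float), "response": response})

    def summary(self) -> str:
        lines = ["Monthly concentration models "
                 f"({self.model.regressor.backend}, n_trees={self.model.regressor.n_trees}, "
                 f"mtry={self.model.regressor.mtry}, min_n={self.model.regressor.min_n})",
                 f"{'month':>5} {'n_train':>8} {'n_test':>7} {'R2_test':>8} {'RMSE_test':>10}"]
        for r in self.reports:
            lines.append(f"{r['month']:>5} {r['n_train']:>8} {r['n_test']:>7} "
                         f"{r.get('r2_test', float('nan')):>8.3f} "
                         f"{r.get('rmse_test', float('nan')):>10.3f}")
        return "\n".join(lines)

    def metrics(self) -> pd.DataFrame:
        return pd.DataFrame([{k: v for k, v in r.items() if k != "importance"}
                             for r in self.reports])
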