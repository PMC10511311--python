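"""Monthly concentration models: recovery, uncertainty, importance,
partial dependence and extrapolation flagging."""

import numpy as np
import pandas as pd
import pytest

from riverch4.concentration import (ConcentrationModel, RegressorConfig,
                                    flag_extrapolation)


def _dataset(n_per_month=150, noise=0.0, seed=0, null=False):
    """Reach-month dataset whose log response is a known function of three
    predictors (plus an unused one)."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for m in range(1, 13):
        for _ in range(n_per_month):
            x1, x2, x3, x4 = rng.normal(0, 1, 4)
            ln_y = rng.normal(0, 1) if null else 1.2 * x1 - 0.8 * x2 + 0.5 * x3
            rows.append({"reach_id": f"r{i:05d}", "month": m,
                         "x1": x1, "x2": x2, "x3": x3, "x4": x4,
                         "c_ch4": float(np.exp(ln_y + rng.normal(0, noise)))})
            i += 1
    return pd.DataFrame(rows)


CFG = RegressorConfig(n_trees=100, mtry=3, min_n=4, seed=0)
PREDICTORS = ["x1", "x2", "x3", "x4"]


@pytest.fixture(scope="module")
def fitted():
    model = ConcentrationModel(_dataset(), PREDICTORS, regressor=CFG, split_seed=1)
    return model.fit()


def test_noiseless_signal_recovered(fitted):
    r2 = [r["r2_test"] for r in fitted.reports]
    assert min(r2) > 0.9


def test_null_response_gives_no_skill():
    model = ConcentrationModel(_dataset(null=True), PREDICTORS,
                               regressor=CFG, split_seed=1)
    res = model.fit()
    assert np.median([r["r2_test"] for r in res.reports]) < 0.2


def test_permutation_importance_separates_used_from_unused(fitted):
    imp = fitted.importance_summary()
    assert imp.loc["x1", "median_importance"] > imp.loc["x4", "median_importance"]
    assert imp.loc["x4", "median_importance"] == pytest.approx(0.0, abs=0.05)
    assert imp.index[0] == "x1"   # strongest planted effect ranks first


def test_metrics_reproducible_with_recorded_seed():
    a = ConcentrationModel(_dataset(), PREDICTORS, regressor=CFG, split_seed=1).fit()
    b = ConcentrationModel(_dataset(), PREDICTORS, regressor=CFG, split_seed=1).fit()
    assert [r["r2_test"] for r in a.reports] == [r["r2_test"] for r in b.reports]


def test_window_too_small_raises():
    tiny = _dataset(n_per_month=1)
    model = ConcentrationModel(tiny, PREDICTORS, regressor=CFG)
    with pytest.raises(ValueError, match="window too small"):
        model.fit()


class TestPredict:
    def test_constant_response_constant_prediction_zero_sd(self):
        data = _dataset()
        data["c_ch4"] = 2.5
        res = ConcentrationModel(data, PREDICTORS, regressor=CFG).fit()
        field = res.predict(data)
        assert np.allclose(field["c_hat"], 2.5)
        assert np.allclose(field["c_sd"], 0.0, atol=1e-8)

    def test_predictions_track_truth(self, fitted):
        data = _dataset(seed=0)
        field = res_field = fitted.predict(data)
        truth = data.set_index(["reach_id", "month"])["c_ch4"]
        joined = res_field.set_index(["reach_id", "month"]).join(truth)
        r = np.corrcoef(np.log(joined["c_hat"]), np.log(joined["c_ch4"]))[0, 1]
        assert r > 0.95

    def test_uncertainty_method_recorded(self, fitted):
        fitted.predict(_dataset().head(50))
        assert fitted.uncertainty_method in ("infinitesimal_jackknife",
                                             "bootstrap_spread")

    def test_sd_grows_far_outside_training_range(self, fitted):
        inside = _dataset(seed=3).head(100)
        outside = inside.copy()
        outside[PREDICTORS] = outside[PREDICTORS] + 6.0
        sd_in = fitted.predict(inside)["c_sd"] / fitted.predict(inside)["c_hat"]
        sd_out = fitted.predict(outside)["c_sd"] / fitted.predict(outside)["c_hat"]
        assert sd_out.mean() > sd_in.mean()

    def test_schema_mismatch_names_missing_columns(self, fitted):
        with pytest.raises(ValueError, match="x4"):
            fitted.predict(_dataset().drop(columns=["x4"]))


class TestExtrapolationFlag:
    def test_training_row_not_flagged(self):
        train = _dataset().head(200)
        flags = flag_extrapolation(train, train.iloc[[5]], PREDICTORS)
        assert not flags[0]

    def test_far_outside_row_flagged(self):
        train = _dataset().head(200)
        row = train.iloc[[0]].copy()
        row["x2"] = 10 * train["x2"].abs().max()
        assert flag_extrapolation(train, row, PREDICTORS)[0]

    def test_in_range_flag_rate_bounded_by_tail_mass(self):
        rng = np.random.default_rng(5)
        train = pd.DataFrame(rng.uniform(0, 1, (2000, 3)), columns=["a", "b", "c"])
        new = pd.DataFrame(rng.uniform(0, 1, (2000, 3)), columns=["a", "b", "c"])
        rate = flag_extrapolation(train, new, ["a", "b", "c"]).mean()
        # union bound: 3 predictors x 2 tails x 1% + sampling slack
        assert rate <= 0.06 + 0.02


class TestPartialDependence:
    def test_linear_effect_slope_recovered(self, fitted):
        curve = fitted.partial_dependence("x1", grid=np.linspace(-1, 1, 9))
        slope = np.polyfit(curve["grid"], curve["response"], 1)[0]
        assert 0.6 * 1.2 < slope < 1.4 * 1.2

    def test_unused_variable_flat(self, fitted):
        curve = fitted.partial_dependence("x4", grid=np.linspace(-1, 1, 9))
        assert np.ptp(curve["response"]) < 0.1

    def test_pd_at_mean_close_to_mean_prediction(self, fitted):
        data = _dataset().groupby("reach_id", as_index=False)[PREDICTORS].mean()
        mean_x1 = float(_dataset()["x1"].mean())
        curve = fitted.partial_dependence("x1", grid=[mean_x1])
        preds = [reg.predict(data[PREDICTORS].to_numpy()).mean()
                 for reg in fitted.models.values()]
        assert curve["response"].iloc[0] == pytest.approx(np.mean(preds), abs=0.15)

    def test_unknown_variable_rejected(self, fitted):
        with pytest.raises(ValueError):
            fitted.partial_dependence("nope")
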