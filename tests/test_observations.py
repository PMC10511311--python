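"""Observation filtering, snapping, aggregation, windows and pruning."""

import numpy as np
import pandas as pd
import pytest

from riverch4.observations import (aggregate_to_reach_month, build_monthly_window,
                                   filter_observations, haversine_m,
                                   prune_predictors, snap_sites)


def _obs(rows):
    return pd.DataFrame(rows)


class TestFilter:
    def _table(self):
        cats = ["normal"] * 7 + ["below_wwtp"] * 3
        return _obs([{"site_id": f"s{i}", "site_category": c, "c_ch4": 1.0}
                     for i, c in enumerate(cats)])

    def test_counts(self):
        retained, report = filter_observations(self._table(), ("below_wwtp",))
        assert len(retained) == 7
        assert report["excluded_by_category"] == {"below_wwtp": 3}

    def test_empty_exclusion_is_identity(self):
        t = self._table()
        retained, report = filter_observations(t, ())
        assert len(retained) == len(t)
        assert report["n_excluded"] == 0

    def test_unknown_category_warns_but_retains(self):
        t = self._table()
        t.loc[0, "site_category"] = "hot_spring"
        with pytest.warns(UserWarning, match="hot_spring"):
            retained, _ = filter_observations(t, ("below_wwtp",),
                                              known_categories=("normal",))
        assert "hot_spring" in set(retained["site_category"])

    def test_order_stability(self):
        t = self._table().sample(frac=1.0, random_state=3)
        retained, report = filter_observations(t, ("below_wwtp",))
        assert report["n_retained"] == 7


class TestSnap:
    def _reaches(self, n=5):
        return pd.DataFrame({"reach_id": [f"r{i}" for i in range(n)],
                             "latitude": np.linspace(40, 41, n),
                             "longitude": np.linspace(10, 11, n)})

    def test_coincident_site_distance_zero(self):
        reaches = self._reaches()
        obs = _obs([{"site_id": "s0", "latitude": 40.0, "longitude": 10.0}])
        out = snap_sites(obs, reaches)
        assert out.loc[0, "reach_id"] == "r0"
        assert out.loc[0, "dist_m"] == pytest.approx(0.0, abs=1e-6)
        assert bool(out.loc[0, "mapped"])

    def test_site_beyond_threshold_unmapped(self):
        reaches = self._reaches()
        # ~600 m north of r0 (0.0054 degrees latitude)
        obs = _obs([{"site_id": "s0", "latitude": 40.0054, "longitude": 10.0}])
        out = snap_sites(obs, reaches, max_dist_m=500.0)
        assert not bool(out.loc[0, "mapped"])
        assert out.loc[0, "dist_m"] > 500

    def test_matches_brute_force_nearest_neighbour(self):
        rng = np.random.default_rng(11)
        reaches = pd.DataFrame({"reach_id": [f"r{i}" for i in range(40)],
                                "latitude": rng.uniform(-60, 60, 40),
                                "longitude": rng.uniform(-170, 170, 40)})
        obs = _obs([{"site_id": f"s{i}", "latitude": la, "longitude": lo}
                    for i, (la, lo) in enumerate(zip(rng.uniform(-60, 60, 100),
                                                     rng.uniform(-170, 170, 100)))])
        out = snap_sites(obs, reaches, max_dist_m=np.inf)
        for row in out.itertuples():
            site = obs[obs["site_id"] == row.site_id].iloc[0]
            d = haversine_m(site["latitude"], site["longitude"],
                            reaches["latitude"], reaches["longitude"])
            assert reaches["reach_id"].iloc[int(np.argmin(d))] == row.reach_id

    def test_no_reaches_errors(self):
        obs = _obs([{"site_id": "s0", "latitude": 0.0, "longitude": 0.0}])
        with pytest.raises(ValueError):
            snap_sites(obs, pd.DataFrame(columns=["reach_id", "latitude", "longitude"]))


class TestAggregate:
    def _mapping(self, sites, reach="rA"):
        return pd.DataFrame({"site_id": sites, "reach_id": reach,
                             "dist_m": 0.0, "mapped": True})

    def test_mean_across_years_then_sites(self):
        obs = _obs([
            {"site_id": "s1", "date": "2010-03-10", "c_ch4": 1.0},
            {"site_id": "s1", "date": "2012-03-20", "c_ch4": 3.0},   # site mean 2.0
            {"site_id": "s2", "date": "2011-03-05", "c_ch4": 4.0},
        ])
        out = aggregate_to_reach_month(obs, self._mapping(["s1", "s2"]))
        assert len(out) == 1
        assert out.loc[0, "c_ch4"] == pytest.approx(3.0)  # mean of 2.0 and 4.0

    def test_median_switch(self):
        obs = _obs([
            {"site_id": "s1", "date": "2010-06-01", "c_ch4": 1.0},
            {"site_id": "s1", "date": "2011-06-01", "c_ch4": 1.0},
            {"site_id": "s1", "date": "2012-06-01", "c_ch4": 100.0},
        ])
        mean_out = aggregate_to_reach_month(obs, self._mapping(["s1"]))
        med_out = aggregate_to_reach_month(obs, self._mapping(["s1"]),
                                           across_years="median")
        assert mean_out.loc[0, "c_ch4"] == pytest.approx(34.0)
        assert med_out.loc[0, "c_ch4"] == pytest.approx(1.0)

    def test_row_count_equals_distinct_reach_months(self, small_study):
        obs = small_study["observations"]
        reaches = small_study["reaches"]
        mapping = snap_sites(obs, reaches)
        out = aggregate_to_reach_month(obs, mapping)
        assert len(out) == len(out.drop_duplicates(["reach_id", "month"]))

    def test_input_order_invariance(self, small_study):
        obs = small_study["observations"]
        mapping = snap_sites(obs, small_study["reaches"])
        a = aggregate_to_reach_month(obs, mapping)
        b = aggregate_to_reach_month(obs.sample(frac=1.0, random_state=9), mapping)
        pd.testing.assert_frame_equal(a, b)


class TestMonthlyWindow:
    def _data(self, n_per_month=20):
        rows = [{"month": m, "v": i} for m in range(1, 13) for i in range(n_per_month)]
        return pd.DataFrame(rows)

    def test_january_window_wraps_to_december(self):
        train, test = build_monthly_window(self._data(), 1)
        assert set(train["month"]) | set(test["month"]) <= {12, 1, 2}
        assert 12 in set(train["month"]) | set(test["month"])

    def test_window_holds_quarter_of_uniform_data(self):
        data = self._data()
        train, test = build_monthly_window(data, 6)
        assert len(train) + len(test) == len(data) // 4

    def test_split_proportions(self):
        train, test = build_monthly_window(self._data(), 6)
        assert abs(len(test) - 0.2 * (len(train) + len(test))) <= 1

    def test_empty_window_raises(self):
        data = pd.DataFrame({"month": [7, 8], "v": [1, 2]})
        with pytest.raises(ValueError):
            build_monthly_window(data, 1)


class TestPrune:
    def _data(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, n)
        return pd.DataFrame({
            "a": a,
            "a_dup": a * 2.0 + 1.0,           # r = 1 with a
            "b": rng.normal(0, 1, n),
            "c": rng.normal(0, 1, n),
            "skewed": rng.lognormal(0, 2, n),  # heavy right skew
            "const": 1.0,
        })

    def test_duplicate_column_removed_and_pairwise_r_bounded(self):
        out, report = prune_predictors(self._data(), ["a", "a_dup", "b", "c"])
        assert "a_dup" not in out.columns
        corr = out[report["kept"]].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.95

    def test_independent_noise_columns_survive(self):
        _, report = prune_predictors(self._data(), ["a", "b", "c"])
        assert set(report["kept"]) == {"a", "b", "c"}

    def test_keep_priority_decides_winner(self):
        _, report = prune_predictors(self._data(), ["a", "a_dup"],
                                     keep_priority=("a_dup",))
        assert report["kept"] == ["a_dup"]

    def test_skew_rule(self):
        data = self._data()
        out, report = prune_predictors(data, ["b", "skewed"], skew_threshold=1.0)
        assert "skewed" in report["log_transformed"]
        assert "b" not in report["log_transformed"]
        assert abs(out["skewed"].skew()) < abs(data["skewed"].skew())

    def test_constant_column_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="const"):
            _, report = prune_predictors(self._data(), ["a", "const"])
        assert report["dropped_constant"] == ["const"]
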