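"""Flux corrections, footprint algebra, upscaling and validation."""

import numpy as np
import pandas as pd
import pytest

from riverch4.fluxes import (SECONDS_PER_DAY, correct_cap_flux, correct_cap_k,
                             correct_supply_limited, footprint_length,
                             upscale, validate_against_measured)
from _helpers import make_reach_row


class TestFootprint:
    def test_direct_evaluation(self):
        # V=0.5 m/s (43,200 m/day), D=1 m, k=10 m/day -> 12,960 m
        assert footprint_length(0.5, 10.0, 1.0) == pytest.approx(12960.0)

    def test_doubling_depth_doubles_footprint(self):
        assert footprint_length(0.5, 10.0, 2.0) \
            == pytest.approx(2 * footprint_length(0.5, 10.0, 1.0))

    def test_halving_k_doubles_footprint(self):
        assert footprint_length(0.5, 5.0, 1.0) \
            == pytest.approx(2 * footprint_length(0.5, 10.0, 1.0))

    def test_requires_positive_k_and_depth(self):
        with pytest.raises(ValueError):
            footprint_length(0.5, 0.0, 1.0)
        with pytest.raises(ValueError):
            footprint_length(0.5, 10.0, 0.0)


class TestSupplyLimited:
    def test_corrected_value_hand_evaluation(self):
        # short reach: k shrinks to 3 * 43,200 * 1 / 5,000 = 25.92 m/day
        assert correct_supply_limited(50.0, 0.5, 1.0, 5000.0) == pytest.approx(25.92)

    def test_long_footprint_leaves_k_unchanged(self):
        # F_L(k=10) = 12,960 m >= R_L -> no supply limitation
        assert correct_supply_limited(10.0, 0.5, 1.0, 12000.0) == 10.0

    def test_footprint_equals_reach_length_after_correction(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0.05, 2.0, 200)
        d = rng.uniform(0.1, 5.0, 200)
        r_l = rng.uniform(500, 20000, 200)
        k = rng.uniform(0.5, 200.0, 200)
        k_c = correct_supply_limited(k, v, d, r_l)
        corrected = k_c < k
        f_l = footprint_length(v[corrected], k_c[corrected], d[corrected])
        assert np.allclose(f_l, r_l[corrected], rtol=1e-12)

    def test_never_increases_k_and_idempotent(self):
        rng = np.random.default_rng(4)
        k = rng.uniform(0.1, 100, 500)
        v = rng.uniform(0.01, 2, 500)
        d = rng.uniform(0.05, 4, 500)
        r_l = rng.uniform(100, 30000, 500)
        once = correct_supply_limited(k, v, d, r_l)
        assert (once <= k + 1e-12).all()
        assert np.allclose(correct_supply_limited(once, v, d, r_l), once)


class TestCapK:
    @pytest.mark.parametrize("k, cap, expected", [
        (50.0, 35.0, 35.0),
        (10.0, 35.0, 10.0),
        (25.0, 20.0, 20.0),
    ])
    def test_cap(self, k, cap, expected):
        assert correct_cap_k(k, cap=cap) == expected

    def test_idempotent(self):
        k = np.array([1.0, 40.0, 80.0])
        assert np.allclose(correct_cap_k(correct_cap_k(k)), correct_cap_k(k))


class TestCapFlux:
    def test_all_equal_population_unchanged(self):
        f = np.full(10, 2.5)
        assert np.allclose(correct_cap_flux(f), f)

    def test_outlier_capped_at_mean_plus_two_sd(self):
        f = np.array([1.0] * 99 + [1000.0])
        mean, sd = f.mean(), f.std(ddof=0)
        out = correct_cap_flux(f)
        assert out[-1] == pytest.approx(mean + 2 * sd)
        assert np.allclose(out[:99], 1.0)
        assert out.max() <= mean + 2 * sd + 1e-12

    def test_single_value_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            out = correct_cap_flux(np.array([3.0]))
        assert out[0] == 3.0


class TestUpscale:
    def test_emission_unit_chain(self, single_reach, flat_concentrations):
        fluxes, totals = upscale(single_reach, flat_concentrations, correction="none")
        june = fluxes[fluxes["month"] == 6].iloc[0]
        # grams = rate (mmol/m2/d) * area * days * 16.04 mg/mmol * 1e-3 g/mg
        expected = june["flux_rate"] * june["effective_area_m2"] * 30 * 16.04e-3
        assert june["emission_g"] == pytest.approx(expected, rel=1e-12)
        assert totals["global_tg_per_yr"] == pytest.approx(
            fluxes["emission_g"].sum() * 1e-12, rel=1e-12)

    def test_known_rate_and_area_gives_half_tonne_month(self, single_reach):
        # plant a 1 mmol/m2/d excess-flux by construction: c_hat - c_eq = 1/k
        fluxes, _ = upscale(single_reach,
                            pd.DataFrame({"reach_id": "r0", "month": range(1, 13),
                                          "c_hat": 1.0}), correction="none")
        june = fluxes[fluxes["month"] == 6].iloc[0]
        rate = june["k_used"] * (1.0 - june["c_eq"])
        area = june["effective_area_m2"]
        # reference arithmetic: area 1e6 m2 at rate 1 for 30 days = 0.4812 t
        assert 1e6 * 1.0 * 30 * 16.04e-3 == pytest.approx(481200.0)
        assert june["emission_g"] == pytest.approx(rate * area * 30 * 16.04e-3)

    def test_supply_limited_totals_never_exceed_uncorrected(self, small_reaches):
        conc = _field(small_reaches, c=1.0)
        _, t_none = upscale(small_reaches, conc, correction="none")
        _, t_sl = upscale(small_reaches, conc, correction="supply_limited")
        assert t_sl["global_tg_per_yr"] <= t_none["global_tg_per_yr"] + 1e-15

    def test_band_totals_conserve_global(self, small_reaches):
        conc = _field(small_reaches, c=0.8)
        _, totals = upscale(small_reaches, conc)
        band_sum = sum(b["emission_tg"] for b in totals["by_band_tg"])
        assert band_sum == pytest.approx(totals["global_tg_per_yr"], rel=1e-9)
        month_sum = sum(totals["by_month_tg"].values())
        assert month_sum == pytest.approx(totals["global_tg_per_yr"], rel=1e-9)

    def test_zero_effective_area_gives_zero_total(self, flat_concentrations):
        frozen = pd.DataFrame([make_reach_row(ice_free=0.0)])
        _, totals = upscale(frozen, flat_concentrations)
        assert totals["global_tg_per_yr"] == 0.0

    def test_missing_months_raise(self, single_reach):
        conc = pd.DataFrame({"reach_id": "r0", "month": [1, 2], "c_hat": 1.0})
        with pytest.raises(ValueError, match="missing modelled concentration"):
            upscale(single_reach, conc)

    def test_mass_balance_under_supply_limitation(self, small_reaches):
        # per-reach evasion never exceeds 3x the advective throughput
        conc = _field(small_reaches, c=2.0)
        fluxes, _ = upscale(small_reaches, conc, correction="supply_limited")
        f = fluxes[fluxes["effective_area_m2"] > 0]
        evasion = f["k_used"] * (f["c_hat"] - f["c_eq"]) * f["w_m"] * \
            f["reach_id"].map(small_reaches.set_index("reach_id")["length_m"])
        throughput = f["c_hat"] * f["v_ms"] * SECONDS_PER_DAY * f["d_m"] * f["w_m"]
        assert (evasion <= 3 * throughput * (1 + 1e-9)).all()


def _field(reaches, c=1.0, sd=0.0):
    rows = []
    for rid in reaches["reach_id"]:
        for m in range(1, 13):
            rows.append({"reach_id": rid, "month": m, "c_hat": c, "c_sd": sd})
    return pd.DataFrame(rows)


class TestValidation:
    def _self_consistent_obs(self, reaches, fluxes, noise_sd=0.0, seed=0):
        """Observations manufactured from the model's own fluxes."""
        rng = np.random.default_rng(seed)
        rows = []
        sample = fluxes[fluxes["flux_rate"] > 0].sample(
            n=min(80, (fluxes["flux_rate"] > 0).sum()), random_state=seed)
        geo = reaches.set_index("reach_id")
        for i, r in enumerate(sample.itertuples()):
            rows.append({
                "site_id": f"v{i:04d}",
                "latitude": geo.loc[r.reach_id, "latitude"],
                "longitude": geo.loc[r.reach_id, "longitude"],
                "date": f"2015-{r.month:02d}-10",
                "c_ch4": 1.0,
                "flux_diff": r.flux_rate * np.exp(rng.normal(0, noise_sd)),
                "k600_measured": r.k600,
                "k_method": "chamber",
                "t_water": 10.0,
                "site_category": "normal",
            })
        return pd.DataFrame(rows)

    def test_self_consistency_recovers_identity(self, small_reaches):
        conc = _field(small_reaches, c=1.0)
        # vary concentration by reach so log fluxes have spread
        rng = np.random.default_rng(1)
        conc["c_hat"] = np.exp(rng.normal(0, 1, len(conc)))
        fluxes, _ = upscale(small_reaches, conc, correction="none")
        obs = self._self_consistent_obs(small_reaches, fluxes)
        out = validate_against_measured(fluxes, obs, small_reaches)
        assert out["slope"] == pytest.approx(1.0, abs=1e-6)
        assert out["r2"] == pytest.approx(1.0, abs=1e-6)

    def test_r2_degrades_with_noise(self, small_reaches):
        conc = _field(small_reaches, c=1.0)
        rng = np.random.default_rng(1)
        conc["c_hat"] = np.exp(rng.normal(0, 1, len(conc)))
        fluxes, _ = upscale(small_reaches, conc, correction="none")
        r2 = []
        for sd in (0.2, 1.0, 3.0):
            obs = self._self_consistent_obs(small_reaches, fluxes, noise_sd=sd, seed=5)
            r2.append(validate_against_measured(fluxes, obs, small_reaches)["r2"])
        assert r2[0] > r2[1] > r2[2]

    def test_excluded_k_methods_are_dropped(self, small_reaches):
        conc = _field(small_reaches, c=1.0)
        fluxes, _ = upscale(small_reaches, conc, correction="none")
        obs = self._self_consistent_obs(small_reaches, fluxes)
        obs["k_method"] = "not determined"
        with pytest.raises(ValueError, match="matched pairs"):
            validate_against_measured(fluxes, obs, small_reaches)

    def test_tight_k_window_keeps_exact_matches_only(self, small_reaches):
        conc = _field(small_reaches, c=1.0)
        rng = np.random.default_rng(2)
        conc["c_hat"] = np.exp(rng.normal(0, 1, len(conc)))
        fluxes, _ = upscale(small_reaches, conc, correction="none")
        obs = self._self_consistent_obs(small_reaches, fluxes)
        # perturb half the measured k600 values out of the exact window
        obs.loc[obs.index[: len(obs) // 2], "k600_measured"] *= 3.0
        out = validate_against_measured(fluxes, obs, small_reaches,
                                        k_ratio_window=(1.0, 1.0))
        assert out["n"] <= len(obs) - len(obs) // 2
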