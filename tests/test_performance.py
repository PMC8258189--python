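"""Performance surfaces, seasonal aggregation, latitude profiles, correlation."""

import numpy as np
import pandas as pd
import pytest

import thermoscape as ts
from thermoscape.dispersal import ScenarioRange
from thermoscape.errors import DataError
from thermoscape.performance import SURFACE_COLUMNS, hemisphere_of
from thermoscape.synthetic_world import CatchmentNetwork, EnvironmentTable
from thermoscape.traits_tpc import TPC, ThermalTraits, tpc_evaluate


def toy_world(lats, temps_by_cid=None, temp_C=16.0):
    """Tiny network + environment with flat (or per-catchment) temperatures."""
    ids = [f"C{i}" for i in range(len(lats))]
    cat = pd.DataFrame(
        {"catchment_id": ids, "region": "R1", "area_km2": 4000.0, "lat": lats, "lon": 0.0}
    )
    net = CatchmentNetwork(catchments=cat, edges=frozenset())
    rows = []
    for cid in ids:
        for period in ("baseline", "future"):
            for m in range(1, 13):
                t = temps_by_cid[cid][m - 1] if temps_by_cid else temp_C
                rows.append(
                    {"catchment_id": cid, "period": period, "month": m, "water_temp_C": t}
                )
    cov = pd.DataFrame({"catchment_id": ids, "name": "altitude", "value": 100.0})
    env = EnvironmentTable(temperature=pd.DataFrame(rows), covariates=cov)
    return net, env


@pytest.fixture
def stage_tpcs():
    return {
        "adult": TPC(ThermalTraits("s", "adult", 0.0, 16.0, 25.0)),
        "juvenile": TPC(ThermalTraits("s", "juvenile", 0.0, 15.0, 24.0)),
        "egg": TPC(ThermalTraits("s", "egg", 0.0, 8.0, 16.0)),
    }


class TestSeasonDefinition:
    def test_default_partitions_year(self):
        ts.SeasonDefinition()  # validates in __post_init__

    def test_non_partition_rejected(self):
        with pytest.raises(ValueError):
            ts.SeasonDefinition(
                seasons={
                    "winter": frozenset({12, 1, 2}),
                    "spring": frozenset({3, 4, 5}),
                    "summer": frozenset({6, 7, 8}),
                    "autumn": frozenset({9, 10}),  # November missing
                }
            )

    def test_spawning_window_must_span_five_months(self):
        with pytest.raises(ValueError):
            ts.SeasonDefinition(spawning_nh=frozenset({10, 11}))

    def test_hemisphere_spawning_windows(self):
        sd = ts.SeasonDefinition()
        assert sd.spawning("N") == frozenset({10, 11, 12, 1, 2})
        assert sd.spawning("S") == frozenset({4, 5, 6, 7, 8})


class TestAssembleSurface:
    def test_optimal_temperature_gives_unit_adult_rates(self, stage_tpcs):
        net, env = toy_world([45.0, 50.0], temp_C=16.0)
        surface = ts.assemble_surface(
            [ScenarioRange("baseline", frozenset({"C0", "C1"}))], env, stage_tpcs, net
        )
        adult = surface[surface["life_stage"] == "adult"]
        assert (adult["rate"] == 1.0).all()
        assert len(adult) == 24

    def test_absent_catchment_has_no_records(self, stage_tpcs):
        net, env = toy_world([45.0, 50.0])
        surface = ts.assemble_surface(
            [ScenarioRange("baseline", frozenset({"C0"}))], env, stage_tpcs, net
        )
        assert set(surface["catchment_id"]) == {"C0"}

    def test_egg_records_follow_hemisphere_spawning_window(self, stage_tpcs):
        net, env = toy_world([45.0, -45.0], temp_C=8.0)
        surface = ts.assemble_surface(
            [ScenarioRange("baseline", frozenset({"C0", "C1"}))], env, stage_tpcs, net
        )
        egg = surface[surface["life_stage"] == "egg"]
        assert set(egg.loc[egg["catchment_id"] == "C0", "month"]) == {10, 11, 12, 1, 2}
        assert set(egg.loc[egg["catchment_id"] == "C1", "month"]) == {4, 5, 6, 7, 8}

    def test_matches_per_cell_manual_evaluation(self, stage_tpcs):
        temps = {
            "C0": list(np.linspace(2, 24, 12)),
            "C1": list(np.linspace(-3, 30, 12)),
            "C2": [16.0] * 12,
        }
        net, env = toy_world([40.0, 50.0, 60.0], temps_by_cid=temps)
        surface = ts.assemble_surface(
            [ScenarioRange("no_dispersal", frozenset(temps))], env, stage_tpcs, net
        )
        for _, row in surface.iterrows():
            expected = tpc_evaluate(
                stage_tpcs[row["life_stage"]], temps[row["catchment_id"]][row["month"] - 1]
            )
            assert row["rate"] == pytest.approx(expected)

    def test_scenario_period_mapping(self, stage_tpcs):
        # baseline scenario reads baseline temps; dispersal scenarios read future
        temps = {"C0": [10.0] * 12}
        net, env = toy_world([40.0], temps_by_cid=temps)
        env_fut = env.temperature.copy()
        env_fut.loc[env_fut["period"] == "future", "water_temp_C"] = 20.0
        env2 = EnvironmentTable(temperature=env_fut, covariates=env.covariates)
        surface = ts.assemble_surface(
            [
                ScenarioRange("baseline", frozenset({"C0"})),
                ScenarioRange("free_dispersal", frozenset({"C0"})),
            ],
            env2,
            {"adult": stage_tpcs["adult"]},
            net,
        )
        base = surface[surface["scenario"] == "baseline"]["rate"].unique()
        fut = surface[surface["scenario"] == "free_dispersal"]["rate"].unique()
        assert base == pytest.approx([tpc_evaluate(stage_tpcs["adult"], 10.0)])
        assert fut == pytest.approx([tpc_evaluate(stage_tpcs["adult"], 20.0)])

    def test_missing_temperature_record_raises(self, stage_tpcs):
        net, env = toy_world([40.0])
        surface_range = [ScenarioRange("baseline", frozenset({"ghost"}))]
        with pytest.raises((DataError, KeyError)):
            ts.assemble_surface(surface_range, env, stage_tpcs, net)


def constant_surface(rate, lats, scenario="baseline", stage="adult"):
    rows = []
    for i, lat in enumerate(lats):
        for m in range(1, 13):
            rows.append((scenario, f"C{i}", stage, m, rate, lat, hemisphere_of(lat)))
    return pd.DataFrame(rows, columns=SURFACE_COLUMNS)


class TestMonthlySummary:
    def test_constant_surface_yields_constant_means(self):
        surface = constant_surface(0.5, [40.0, 50.0])
        out = ts.monthly_summary(surface, "N")
        assert (out["mean_rate"] == 0.5).all()
        assert len(out) == 12

    def test_single_catchment_means_equal_series(self):
        surface = constant_surface(0.3, [40.0])
        surface.loc[surface["month"] == 6, "rate"] = 0.9
        out = ts.monthly_summary(surface, "N").set_index("month")["mean_rate"]
        assert out[6] == 0.9 and out[1] == 0.3

    def test_two_catchments_average(self):
        surface = pd.concat(
            [constant_surface(0.2, [40.0]), constant_surface(0.6, [50.0])], ignore_index=True
        )
        surface.loc[surface["catchment_id"] == "C0", "catchment_id"] = "A"
        out = ts.monthly_summary(surface, "N")
        assert out["mean_rate"].unique() == pytest.approx([0.4])

    def test_empty_hemisphere_warns_and_returns_empty(self):
        surface = constant_surface(0.5, [40.0])
        with pytest.warns(UserWarning, match="hemisphere"):
            out = ts.monthly_summary(surface, "S")
        assert out.empty


class TestSeasonalSummary:
    def test_constant_surface_all_timeframes_constant(self):
        surface = constant_surface(0.5, [40.0, 55.0])
        out = ts.seasonal_summary(surface, hemisphere="N")
        assert (out["mean_rate"] == 0.5).all()
        assert set(out["timeframe"]) == {"winter", "spring", "summer", "autumn", "annual"}

    def test_annual_equals_mean_of_seasonal_means_in_balanced_design(self):
        rng = np.random.default_rng(0)
        surface = constant_surface(0.0, [40.0, 50.0, 60.0])
        surface["rate"] = rng.random(len(surface))
        out = ts.seasonal_summary(surface, hemisphere="N").set_index("timeframe")
        seasons = out.loc[["winter", "spring", "summer", "autumn"], "mean_rate"]
        assert out.loc["annual", "mean_rate"] == pytest.approx(seasons.mean())

    def test_hand_computed_seasonal_means(self):
        surface = constant_surface(0.2, [40.0])
        surface.loc[surface["month"].isin([6, 7, 8]), "rate"] = 0.8
        out = ts.seasonal_summary(surface, hemisphere="N").set_index("timeframe")
        assert out.loc["summer", "mean_rate"] == pytest.approx(0.8)
        assert out.loc["winter", "mean_rate"] == pytest.approx(0.2)
        assert out.loc["annual", "mean_rate"] == pytest.approx((3 * 0.8 + 9 * 0.2) / 12)

    def test_southern_labels_carry_local_season(self):
        surface = constant_surface(0.5, [-40.0])
        out = ts.seasonal_summary(surface, hemisphere="S")
        labels = dict(zip(out["timeframe"], out["label"]))
        assert labels["winter"] == "winter (summer)"
        assert labels["summer"] == "summer (winter)"

    def test_egg_rows_report_spawning_only(self):
        surface = constant_surface(0.4, [40.0], stage="egg")
        surface = surface[surface["month"].isin([10, 11, 12, 1, 2])]
        out = ts.seasonal_summary(surface, hemisphere="N")
        assert list(out["timeframe"]) == ["spawning"]
        assert out["mean_rate"].iloc[0] == pytest.approx(0.4)


class TestLatitudinalProfile:
    def test_single_bin_holds_overall_mean(self):
        surface = constant_surface(0.0, [40.1, 40.2, 40.3])
        rng = np.random.default_rng(1)
        surface["rate"] = rng.random(len(surface))
        out = ts.latitudinal_profile(surface, bin_width_deg=5.0)
        assert len(out) == 1
        per_catchment = surface.groupby("catchment_id")["rate"].mean()
        assert out["mean_annual_rate"].iloc[0] == pytest.approx(per_catchment.mean())

    def test_fine_bins_recover_per_catchment_means(self):
        surface = constant_surface(0.0, [40.0, 47.0, 54.0])
        rng = np.random.default_rng(2)
        surface["rate"] = rng.random(len(surface))
        out = ts.latitudinal_profile(surface, bin_width_deg=1.0)
        assert len(out) == 3
        assert (out["n_catchments"] == 1).all()

    def test_hand_binned_means(self):
        lats = [40.0, 41.0, 48.0]
        surface = constant_surface(0.0, lats)
        surface["rate"] = surface["catchment_id"].map({"C0": 0.2, "C1": 0.4, "C2": 0.9})
        out = ts.latitudinal_profile(surface, bin_width_deg=5.0).set_index("lat_bin_center")
        assert out.loc[42.5, "mean_annual_rate"] == pytest.approx(0.3)  # C0, C1 in [40,45)
        assert out.loc[47.5, "mean_annual_rate"] == pytest.approx(0.9)

    def test_invalid_width_raises(self):
        with pytest.raises(ValueError):
            ts.latitudinal_profile(constant_surface(0.5, [40.0]), bin_width_deg=0.0)


class TestSuitabilityPerformanceCorrelation:
    def _surface_with_rates(self, rates):
        surface = constant_surface(0.0, [40.0 + i for i in range(len(rates))])
        surface["rate"] = surface["catchment_id"].map(
            {f"C{i}": r for i, r in enumerate(rates)}
        )
        return surface

    def test_identical_vectors_give_unit_correlation(self):
        rates = [0.1, 0.4, 0.7, 0.9]
        surface = self._surface_with_rates(rates)
        probs = pd.Series(rates, index=[f"C{i}" for i in range(4)])
        out = ts.suitability_performance_correlation(probs, surface, "adult")
        assert out["r"] == pytest.approx(1.0)
        assert out["n"] == 4

    def test_reversed_vectors_give_negative_unit(self):
        rates = [0.1, 0.4, 0.7, 0.9]
        surface = self._surface_with_rates(rates)
        probs = pd.Series([1 - r for r in rates], index=[f"C{i}" for i in range(4)])
        out = ts.suitability_performance_correlation(probs, surface, "adult")
        assert out["r"] == pytest.approx(-1.0)

    def test_matches_closed_form_pearson(self):
        rng = np.random.default_rng(3)
        rates = rng.random(10)
        surface = self._surface_with_rates(rates)
        probs = pd.Series(rng.random(10), index=[f"C{i}" for i in range(10)])
        out = ts.suitability_performance_correlation(probs, surface, "adult")
        x, y = probs.to_numpy(), rates
        r_manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert out["r"] == pytest.approx(r_manual)

    def test_zero_variance_raises(self):
        surface = self._surface_with_rates([0.5, 0.5, 0.5])
        probs = pd.Series([0.1, 0.5, 0.9], index=["C0", "C1", "C2"])
        with pytest.raises(DataError, match="variance"):
            ts.suitability_performance_correlation(probs, surface, "adult")

    def test_too_few_pairs_raise(self):
        surface = self._surface_with_rates([0.2, 0.8])
        probs = pd.Series([0.1, 0.9], index=["C0", "C1"])
        with pytest.raises(DataError, match="3"):
            ts.suitability_performance_correlation(probs, surface, "adult")


class TestOrderInvariance:
    def test_summaries_invariant_to_row_order(self):
        rng = np.random.default_rng(4)
        surface = constant_surface(0.0, [40.0, 50.0, -45.0])
        surface["rate"] = rng.random(len(surface))
        shuffled = surface.sample(frac=1.0, random_state=5).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            ts.monthly_summary(surface, "N"), ts.monthly_summary(shuffled, "N")
        )
        pd.testing.assert_frame_equal(
            ts.seasonal_summary(surface, hemisphere="N"),
            ts.seasonal_summary(shuffled, hemisphere="N"),
        )
        pd.testing.assert_frame_equal(
            ts.latitudinal_profile(surface), ts.latitudinal_profile(shuffled)
        )
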