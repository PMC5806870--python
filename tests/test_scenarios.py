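import numpy as np
import pandas as pd
import pytest

from sedscape.params import (
    EUCALYPTUS,
    FOREST,
    GROWING_FOREST,
    MICRODAM,
    PASTURE,
    ROAD,
)
from sedscape.raster import Raster
from sedscape.scenarios import (
    Scenario,
    anthropized,
    compare_strategies,
    riparian_scenario,
    scenario_series,
    steepest_scenario,
    two_way_scenario,
)


def landuse_grid(codes) -> Raster:
    return Raster(np.asarray(codes, dtype=float), 5.0)


@pytest.fixture
def mixed_map():
    return landuse_grid([
        [PASTURE, FOREST, FOREST, ROAD],
        [PASTURE, GROWING_FOREST, MICRODAM, ROAD],
        [EUCALYPTUS, PASTURE, PASTURE, PASTURE],
    ])


class TestAnthropized:
    def test_forest_and_dams_become_pasture(self, mixed_map):
        scen = anthropized(mixed_map)
        vals = scen.landuse.values.astype(int)
        assert not np.isin(vals, (FOREST, GROWING_FOREST, MICRODAM)).any()
        assert scen.forest_fraction == 0.0

    def test_roads_and_eucalyptus_persist(self, mixed_map):
        scen = anthropized(mixed_map)
        vals = scen.landuse.values.astype(int)
        assert vals[0, 3] == ROAD and vals[1, 3] == ROAD
        assert vals[2, 0] == EUCALYPTUS

    def test_no_forest_map_unchanged(self):
        lu = landuse_grid([[PASTURE, ROAD], [PASTURE, EUCALYPTUS]])
        scen = anthropized(lu)
        np.testing.assert_array_equal(scen.landuse.values, lu.values)


class TestRiparian:
    def setup_method(self):
        # 11-column pasture strip with a central stream column.
        self.lu = landuse_grid(np.full((3, 11), PASTURE))
        dist = np.abs(np.arange(11) - 5)[None, :] * 5.0
        self.dist = Raster(np.tile(dist, (3, 1)), 5.0)
        self.base = Scenario("base", self.lu, "anthropized")

    def test_width_zero_converts_stream_column_only(self):
        scen = riparian_scenario(self.base, self.dist, 0.0)
        vals = scen.landuse.values.astype(int)
        assert (vals[:, 5] == FOREST).all()
        assert (vals[:, :5] == PASTURE).all()

    def test_width_5m_converts_adjacent_columns(self):
        scen = riparian_scenario(self.base, self.dist, 5.0)
        vals = scen.landuse.values.astype(int)
        assert (vals[:, 4:7] == FOREST).all()
        assert (vals[:, 3] == PASTURE).all() and (vals[:, 7] == PASTURE).all()

    def test_fraction_non_decreasing_in_width(self):
        fracs = [
            riparian_scenario(self.base, self.dist, w).forest_fraction
            for w in (0, 5, 10, 20, 30)
        ]
        assert fracs == sorted(fracs)

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError, match="width"):
            riparian_scenario(self.base, self.dist, -1.0)


class TestSteepest:
    def setup_method(self):
        self.lu = landuse_grid(np.full((4, 4), PASTURE))
        self.slope = Raster(
            np.linspace(0, 90, 16).reshape(4, 4), 5.0
        )
        self.base = Scenario("base", self.lu, "anthropized")

    def test_threshold_above_max_unchanged(self):
        scen = steepest_scenario(self.base, self.slope, 95.0)
        np.testing.assert_array_equal(scen.landuse.values, self.lu.values)

    def test_threshold_zero_converts_everything_convertible(self):
        scen = steepest_scenario(self.base, self.slope, 0.0)
        vals = scen.landuse.values.astype(int)
        assert (vals[self.slope.values > 0] == FOREST).all()

    def test_fraction_non_increasing_in_threshold(self):
        fracs = [
            steepest_scenario(self.base, self.slope, t).forest_fraction
            for t in (0, 30, 60, 95)
        ]
        assert fracs == sorted(fracs, reverse=True)


class TestTwoWay:
    def test_union_of_mechanisms(self):
        lu = landuse_grid(np.full((3, 9), PASTURE))
        dist = Raster(
            np.tile(np.abs(np.arange(9) - 4)[None, :] * 5.0, (3, 1)), 5.0
        )
        slope = Raster(np.zeros((3, 9)), 5.0)
        slope.values[:, 0] = 80.0
        base = Scenario("base", lu, "anthropized")
        scen = two_way_scenario(base, dist, slope, 5.0, 60.0)
        rip = riparian_scenario(base, dist, 5.0)
        steep = steepest_scenario(base, slope, 60.0)
        both = (rip.landuse.values == FOREST) | (steep.landuse.values == FOREST)
        np.testing.assert_array_equal(scen.landuse.values == FOREST, both)

    def test_degenerate_parameters_unchanged(self):
        lu = landuse_grid(np.full((3, 3), PASTURE))
        dist = Raster(np.full((3, 3), 50.0), 5.0)
        slope = Raster(np.full((3, 3), 10.0), 5.0)
        base = Scenario("base", lu, "anthropized")
        scen = two_way_scenario(base, dist, slope, 0.0, 1e9)
        np.testing.assert_array_equal(scen.landuse.values, lu.values)


class TestScenarioSeries:
    def test_targets_reached_on_bundle(self, mini_bundle):
        base = anthropized(mini_bundle.landuse)
        for strategy in ("riparian", "steepest", "two_way"):
            series = scenario_series(
                strategy, base, mini_bundle.dist_to_stream,
                mini_bundle.slope, [25.0],
            )
            assert len(series) == 1
            assert series[0].forest_fraction == pytest.approx(25.0, abs=1.0)

    def test_zero_target_returns_base(self, mini_bundle):
        base = anthropized(mini_bundle.landuse)
        series = scenario_series(
            "riparian", base, mini_bundle.dist_to_stream,
            mini_bundle.slope, [0.0],
        )
        np.testing.assert_array_equal(
            series[0].landuse.values, base.landuse.values
        )

    def test_unreachable_target_raises_with_maximum(self, mini_bundle):
        base = anthropized(mini_bundle.landuse)
        with pytest.raises(ValueError, match="maximum"):
            scenario_series(
                "riparian", base, mini_bundle.dist_to_stream,
                mini_bundle.slope, [99.0],
            )

    def test_unsorted_targets_rejected(self, mini_bundle):
        base = anthropized(mini_bundle.landuse)
        with pytest.raises(ValueError, match="increasing"):
            scenario_series(
                "riparian", base, mini_bundle.dist_to_stream,
                mini_bundle.slope, [25.0, 10.0],
            )

    def test_maps_differ_only_on_convertible_classes(self, mini_bundle):
        base = anthropized(mini_bundle.landuse)
        series = scenario_series(
            "two_way", base, mini_bundle.dist_to_stream,
            mini_bundle.slope, [25.0],
        )
        changed = series[0].landuse.values != base.landuse.values
        before = base.landuse.values[changed].astype(int)
        assert np.isin(before, (PASTURE, EUCALYPTUS)).all()
        assert (series[0].landuse.values[changed] == FOREST).all()


class TestCompareStrategies:
    def test_baseline_scenario_zero_reduction(self, strategy_comparison):
        curves, baseline = strategy_comparison
        from sedscape.scenarios import StrategyCurve
        rows = []
        for _, b in baseline.iterrows():
            rows.append({
                "scenario": "same", "parameter": "", "forest_fraction": 0.0,
                "member": b["member"], "soil_loss": b["soil_loss"],
                "sediment_export": b["sediment_export"],
            })
        identical = {"x": StrategyCurve("x", pd.DataFrame(rows))}
        out = compare_strategies(identical, baseline)
        assert out["export_reduction_mean"].iloc[0] == pytest.approx(0.0)
        assert out["soil_loss_reduction_mean"].iloc[0] == pytest.approx(0.0)

    def test_reductions_bounded_when_only_adding_forest(
        self, strategy_comparison
    ):
        curves, baseline = strategy_comparison
        out = compare_strategies(curves, baseline)
        assert (out["export_reduction_min"] >= 0.0).all()
        assert (out["export_reduction_max"] <= 100.0).all()
        assert (out["soil_loss_reduction_min"] >= 0.0).all()

    def test_mechanism_ordering_at_equal_forest(self, strategy_comparison):
        curves, baseline = strategy_comparison
        out = compare_strategies(curves, baseline)
        at25 = {
            s: out[(out.strategy == s)
                   & ((out.forest_fraction - 25).abs() < 2)].iloc[0]
            for s in ("riparian", "steepest", "two_way")
        }
        assert (at25["riparian"]["export_reduction_mean"]
                > at25["two_way"]["export_reduction_mean"]
                > at25["steepest"]["export_reduction_mean"])
        assert (at25["steepest"]["soil_loss_reduction_mean"]
                > at25["two_way"]["soil_loss_reduction_mean"]
                > at25["riparian"]["soil_loss_reduction_mean"])

    def test_zero_baseline_rejected(self, strategy_comparison):
        curves, baseline = strategy_comparison
        bad = baseline.copy()
        bad["sediment_export"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            compare_strategies(curves, bad)
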