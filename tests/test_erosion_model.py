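import numpy as np
import pytest

from sedscape import terrain
from sedscape.erosion_model import (
    build_param_rasters,
    route_sediment,
    summarize_by_slope,
    usle,
)
from sedscape.params import (
    EUCALYPTUS,
    FOREST,
    GROWING_FOREST,
    MICRODAM,
    PASTURE,
    ROAD,
    erodibility_lookup,
    resolve_landuse_params,
)
from sedscape.raster import Raster

from conftest import plane_dem, random_flow_grid


def brute_force_export(soil_loss, sre, flow):
    """Naive per-source path-product enumeration (independent oracle)."""
    ny, nx = soil_loss.shape
    e = sre.values.ravel()
    stream = flow.streams.ravel()
    down = flow.downstream
    exported = 0.0
    for i in range(ny * nx):
        if flow.direction.ravel()[i] == terrain.NODATA_DIR:
            continue
        mass = soil_loss.values.ravel()[i] * soil_loss.cell_area_ha
        if stream[i]:
            exported += mass
            continue
        j = down[i]
        while j >= 0 and not stream[j]:
            mass *= 1.0 - e[j]
            j = down[j]
        exported += mass
    return exported


class TestUsle:
    def grids(self, val, shape=(3, 3), cell=5.0):
        return Raster(np.full(shape, val), cell)

    def test_direct_product(self):
        a = usle(self.grids(6873.0), self.grids(0.0252), self.grids(1.0),
                 self.grids(0.22), self.grids(1.0))
        np.testing.assert_allclose(a.values, 6873 * 0.0252 * 0.22)
        assert a.values[0, 0] == pytest.approx(38.10, abs=0.01)

    def test_zero_cover_zero_loss(self):
        a = usle(self.grids(6873.0), self.grids(0.03), self.grids(2.0),
                 self.grids(0.0), self.grids(1.0))
        np.testing.assert_array_equal(a.values, 0.0)

    def test_linear_in_ls(self):
        args = (self.grids(5000.0), self.grids(0.02))
        rest = (self.grids(0.1), self.grids(1.0))
        a1 = usle(*args, self.grids(1.0), *rest)
        a2 = usle(*args, self.grids(2.0), *rest)
        np.testing.assert_allclose(a2.values, 2 * a1.values)

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            usle(self.grids(1.0), Raster(np.ones((4, 4)), 5.0),
                 self.grids(1.0), self.grids(1.0), self.grids(1.0))

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            usle(self.grids(1.0), self.grids(-0.1), self.grids(1.0),
                 self.grids(1.0), self.grids(1.0))


class TestRouteSediment:
    def chain(self, n=6, cell=100.0):
        """1-D west-east chain; last two cells are stream."""
        dem = plane_dem(1, n, dzdx=-1.0, cell=cell)
        flow = terrain.d8_flow(terrain.fill_depressions(dem), threshold=n - 2)
        return dem, flow

    def test_homogeneous_buffer_closed_form(self):
        dem, flow = self.chain()
        a = np.array([[10.0, 0, 0, 0, 0, 0]]) / dem.cell_area_ha
        e = np.array([[0.0, 0.65, 0.65, 0.65, 0, 0]])
        out = route_sediment(dem.like(a), dem.like(e), flow)
        assert out.exported_total == pytest.approx(10 * 0.35**3, rel=1e-12)
        assert out.retained_total == pytest.approx(10 * (1 - 0.35**3), rel=1e-12)

    def test_own_cell_retention_not_applied(self):
        dem, flow = self.chain()
        a = np.array([[10.0, 0, 0, 0, 0, 0]]) / dem.cell_area_ha
        e = np.array([[1.0, 0, 0, 0, 0, 0]])  # E on the source cell only
        out = route_sediment(dem.like(a), dem.like(e), flow)
        assert out.exported_total == pytest.approx(10.0)

    def test_no_trapping_exports_everything(self, rng):
        filled, flow = random_flow_grid(3)
        a = filled.like(rng.random(filled.shape) * 30)
        e = filled.like(np.zeros(filled.shape))
        out = route_sediment(a, e, flow)
        total = a.values.sum() * a.cell_area_ha
        assert out.exported_total == pytest.approx(total, rel=1e-12)
        assert out.retained_total == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_random_grids(self, seed):
        rng = np.random.default_rng(seed + 1000)
        filled, flow = random_flow_grid(seed)
        a = filled.like(rng.random(filled.shape) * 50)
        e = filled.like(rng.random(filled.shape) * 0.95)
        out = route_sediment(a, e, flow)
        oracle = brute_force_export(a, e, flow)
        assert out.exported_total == pytest.approx(oracle, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_mass_conservation(self, seed):
        rng = np.random.default_rng(seed)
        filled, flow = random_flow_grid(seed)
        a = filled.like(rng.random(filled.shape) * 50)
        e = filled.like(rng.random(filled.shape))
        out = route_sediment(a, e, flow)
        total = a.values.sum() * a.cell_area_ha
        assert out.exported_total + out.retained_total == pytest.approx(
            total, rel=1e-9
        )

    def test_source_export_sums_to_exported_total(self, rng):
        filled, flow = random_flow_grid(11)
        a = filled.like(rng.random(filled.shape) * 50)
        e = filled.like(rng.random(filled.shape) * 0.9)
        out = route_sediment(a, e, flow)
        assert out.source_export.values.sum() == pytest.approx(
            out.exported_total, rel=1e-9
        )

    def test_monotone_in_retention(self, rng):
        filled, flow = random_flow_grid(5)
        a = filled.like(rng.random(filled.shape) * 50)
        e_vals = rng.random(filled.shape) * 0.5
        base = route_sediment(a, filled.like(e_vals), flow)
        bumped = e_vals.copy()
        # Raise E on a cell that receives inflow.
        recv = np.unravel_index(
            base.upstream_retention.values.argmax(), filled.shape
        )
        bumped[recv] = min(e_vals[recv] + 0.3, 1.0)
        out = route_sediment(a, filled.like(bumped), flow)
        assert out.exported_total <= base.exported_total

    def test_monotone_in_soil_loss(self, rng):
        filled, flow = random_flow_grid(6)
        a_vals = rng.random(filled.shape) * 50
        e = filled.like(rng.random(filled.shape) * 0.5)
        base = route_sediment(filled.like(a_vals), e, flow)
        a_vals[2, 2] *= 3.0
        out = route_sediment(filled.like(a_vals), e, flow)
        assert out.exported_total >= base.exported_total

    def test_bad_efficiency_rejected(self):
        dem, flow = self.chain()
        a = dem.like(np.ones(dem.shape))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            route_sediment(a, dem.like(np.full(dem.shape, 1.5)), flow)

    def test_outlet_export_normalized_by_area(self, rng):
        filled, flow = random_flow_grid(8)
        a = filled.like(rng.random(filled.shape) * 10)
        e = filled.like(np.zeros(filled.shape))
        out = route_sediment(a, e, flow)
        assert out.outlet_export == pytest.approx(
            out.exported_total / filled.valid_area_ha
        )


class TestBuildParamRasters:
    def maps(self):
        soil = Raster(np.array([[1.0, 2.0], [3.0, 4.0]]), 5.0)
        lu = Raster(
            np.array([[PASTURE, FOREST], [MICRODAM, ROAD]], dtype=float), 5.0
        )
        return soil, lu

    def params(self, pasture_c=0.200, forest_c=0.082):
        return resolve_landuse_params(
            pasture_c=pasture_c, forest_c=forest_c, eucalyptus_c=0.2,
            pasture_sre=0.10, forest_sre=0.45,
        )

    def test_lookup_values(self):
        soil, lu = self.maps()
        k, c, p, e = build_param_rasters(
            soil, lu, erodibility_lookup("mean"), self.params()
        )
        assert k.values[0, 0] == pytest.approx(0.0252)  # red-yellow ultisol
        assert k.values[0, 1] == pytest.approx(0.0245)  # ochrept
        assert c.values[0, 0] == pytest.approx(0.200)
        assert (p.values == 1.0).all()

    def test_growing_forest_mean_of_pasture_and_forest(self):
        params = self.params()
        assert params.c_factor[GROWING_FOREST] == pytest.approx(0.141)

    def test_microdam_total_retention_no_erosion(self):
        soil, lu = self.maps()
        _, c, _, e = build_param_rasters(
            soil, lu, erodibility_lookup("mean"), self.params()
        )
        assert c.values[1, 0] == 0.0
        assert e.values[1, 0] == 1.0

    def test_road_bare_soil(self):
        soil, lu = self.maps()
        _, c, _, e = build_param_rasters(
            soil, lu, erodibility_lookup("mean"), self.params()
        )
        assert c.values[1, 1] == 1.0
        assert e.values[1, 1] == 0.0

    def test_unknown_class_rejected(self):
        soil, lu = self.maps()
        lu.values[0, 0] = 99
        with pytest.raises(KeyError, match="99"):
            build_param_rasters(soil, lu, erodibility_lookup("mean"),
                                self.params())


class TestSummarizeBySlope:
    def run_toy(self, rng):
        filled, flow = random_flow_grid(4)
        a = filled.like(rng.random(filled.shape) * 20)
        e = filled.like(rng.random(filled.shape) * 0.8)
        out = route_sediment(a, e, flow)
        slope = terrain.slope_percent(filled)
        return out, slope

    def test_single_bin_equals_totals(self, rng):
        out, slope = self.run_toy(rng)
        table = summarize_by_slope(out, slope, [0.0, 1e9])
        total_mass = out.soil_loss.values.sum() * out.soil_loss.cell_area_ha
        assert table["soil_loss_mg"].sum() == pytest.approx(total_mass)
        assert table["export_mg"].iloc[0] == pytest.approx(out.exported_total)
        assert table["upstream_retention_mg"].iloc[0] == pytest.approx(
            out.retained_total
        )

    def test_uniform_slope_lands_in_one_bin(self):
        dem = plane_dem(5, 8, dzdx=-0.20)
        flow = terrain.d8_flow(terrain.fill_depressions(dem), threshold=100)
        a = dem.like(np.ones(dem.shape))
        out = route_sediment(a, dem.like(np.zeros(dem.shape)), flow)
        table = summarize_by_slope(
            out, terrain.slope_percent(dem), [0.0, 15.0, 50.0]
        )
        assert table["soil_loss_mg"].iloc[0] == 0.0
        assert table["soil_loss_mg"].iloc[1] > 0.0

    def test_per_bin_export_sums_to_outlet_mass(self, rng):
        out, slope = self.run_toy(rng)
        table = summarize_by_slope(out, slope, [0, 10, 20, 40, 1e9])
        assert table["export_mg"].sum() == pytest.approx(
            out.exported_total, rel=1e-9
        )

    def test_unsorted_edges_rejected(self, rng):
        out, slope = self.run_toy(rng)
        with pytest.raises(ValueError, match="increasing"):
            summarize_by_slope(out, slope, [0.0, 30.0, 15.0])
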