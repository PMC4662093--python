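import math

import numpy as np
import pytest
from shapely.geometry import LineString, box

from geocov.buffers import (
    BufferSpec,
    areal_weighted_sum,
    areal_weighted_sum_over,
    buffer_disc,
    buffer_road_sum,
    emission_buffer_sum,
    emission_cells_to_polygons,
    land_use_proportion,
    road_sum_in_buffer,
)
from geocov.errors import ConfigurationError
from geocov.model import (
    EmissionCell,
    EmissionGridTable,
    Feature,
    LAND_USE_CLASSES,
    MonitoringSite,
    RoadSegment,
    WidthTable,
    ZonalPolygonLayer,
)
from geocov.synthetic import random_counts_layer, random_road_segments
from oracles import mc_areal_sum, mc_class_area_fraction, sampled_road_length

SITE = MonitoringSite("s", 0.0, 0.0)


def straight_road(lanes=2, speed=60.0, highway=False, road_type="district_road"):
    return RoadSegment(
        "r0", LineString([(-5000, 0), (5000, 0)]), road_type, lanes, speed, highway
    )


class TestBufferSpec:
    def test_radii_must_increase(self):
        with pytest.raises(ConfigurationError):
            BufferSpec("traffic", (100.0, 50.0))

    def test_radii_positive(self):
        with pytest.raises(ConfigurationError):
            BufferSpec("traffic", (0.0, 50.0))


class TestBufferDisc:
    def test_area_within_discretization_bound(self):
        # inscribed regular 256-gon: relative deficit 1 - sinc(2*pi/256),
        # about 1.004e-4 (~0.01%)
        bound = 1.0 - math.sin(2 * math.pi / 256) / (2 * math.pi / 256)
        for r in (25.0, 300.0, 30000.0):
            disc = buffer_disc(SITE, r)
            exact = math.pi * r**2
            assert exact > disc.area >= exact * (1.0 - 1.01 * bound)

    def test_vertex_count(self):
        disc = buffer_disc(SITE, 300.0)
        assert len(disc.exterior.coords) - 1 == 256


class TestRoadSum:
    def test_diameter_chord(self):
        # straight road through the site center: clipped length = 2r
        for r in (25.0, 300.0, 1000.0):
            v = road_sum_in_buffer(SITE, r, [straight_road()])
            assert v == pytest.approx(2 * r, rel=1e-9)

    def test_multiplicative_weightings(self):
        r = 300.0
        road = straight_road(lanes=4)
        lane_v = road_sum_in_buffer(SITE, r, [road], weighting="length_x_lanes")
        assert lane_v == pytest.approx(2 * r * 4, rel=1e-9)
        width_table = WidthTable([
            __import__("geocov.model", fromlist=["WidthRow"]).WidthRow(False, 0.0, 121.0, False, 3.0)
        ])
        urbanized = ZonalPolygonLayer([], layer_kind="urbanized_area")
        w_v = road_sum_in_buffer(
            SITE, r, [road], weighting="length_x_lanes_x_width",
            width_table=width_table, urbanized=urbanized,
        )
        assert w_v == pytest.approx(2 * r * 4 * 3.0, rel=1e-9)

    def test_empty_intersection_is_zero(self):
        far = RoadSegment(
            "far", LineString([(9000, 9000), (9500, 9000)]),
            "district_road", 2, 60.0, False,
        )
        assert road_sum_in_buffer(SITE, 100.0, [far]) == 0.0

    def test_matches_sampling_oracle_on_random_scene(self, rng):
        extent = (0.0, 0.0, 200.0, 200.0)
        segments = random_road_segments(rng, extent, 30)
        site = MonitoringSite("s", 100.0, 100.0)
        r = 60.0
        value = road_sum_in_buffer(site, r, segments)
        oracle = sampled_road_length(site.x, site.y, r, segments, step=0.1)
        assert value == pytest.approx(oracle, rel=0.005)

    def test_units_scale(self):
        summary = buffer_road_sum(SITE, 500.0, [straight_road()], weighting="length")
        assert summary.value == pytest.approx(1.0)  # 1000 m -> 1 km

    def test_monotone_in_radius(self, rng):
        segments = random_road_segments(rng, (0.0, 0.0, 500.0, 500.0), 20)
        site = MonitoringSite("s", 250.0, 250.0)
        values = [road_sum_in_buffer(site, r, segments) for r in (25, 50, 100, 200)]
        assert values == sorted(values)


class TestArealWeightedSum:
    def test_buffer_inside_one_polygon(self):
        # value = count * area(buffer) / area(polygon)
        poly = box(-1000, -1000, 1000, 1000)
        zones = ZonalPolygonLayer(
            [Feature("z", poly, {"pop": 100.0})], layer_kind="census"
        )
        r = 300.0
        out = areal_weighted_sum(SITE, r, zones, "pop")
        disc_area = buffer_disc(SITE, r).area
        assert out.value == pytest.approx(100.0 * disc_area / poly.area, rel=1e-12)

    def test_polygon_inside_buffer_contributes_fully(self):
        poly = box(-10, -10, 10, 10)
        zones = ZonalPolygonLayer(
            [Feature("z", poly, {"pop": 100.0})], layer_kind="census"
        )
        out = areal_weighted_sum(SITE, 300.0, zones, "pop")
        assert out.value == pytest.approx(100.0)

    def test_half_plane_split_matches_monte_carlo(self, rng):
        zones = ZonalPolygonLayer(
            [
                Feature("west", box(-1000, -1000, 0, 1000), {"pop": 60.0}),
                Feature("east", box(0, -1000, 1000, 1000), {"pop": 40.0}),
            ],
            layer_kind="census",
        )
        r = 300.0
        value = areal_weighted_sum(SITE, r, zones, "pop").value
        est, sigma = mc_areal_sum(rng, SITE.x, SITE.y, r, zones, "pop", n=10**6)
        assert abs(value - est) <= 3 * sigma

    def test_touching_polygon_contributes_nothing(self):
        # polygon sharing only a boundary point with the buffer
        poly = box(300, -10, 400, 10)
        zones = ZonalPolygonLayer(
            [Feature("z", poly, {"pop": 1000.0})], layer_kind="census"
        )
        out = areal_weighted_sum(SITE, 300.0, zones, "pop")
        assert out.value == 0.0

    def test_conservation_over_tiling_regions(self, rng):
        # areal-weighted sums over square regions that tile the layer
        # extent must add up to the layer's attribute total
        zones = random_counts_layer(rng, (0, 0, 300, 300), 100.0, "count")
        total = sum(f.attributes["count"] for f in zones)
        tiles = [
            box(x, y, x + 150.0, y + 150.0)
            for x in (0.0, 150.0)
            for y in (0.0, 150.0)
        ]
        s = sum(areal_weighted_sum_over(t, zones, "count") for t in tiles)
        assert s == pytest.approx(total, rel=1e-9)

    def test_monotone_in_radius(self, rng):
        zones = random_counts_layer(rng, (-500, -500, 500, 500), 200.0, "count")
        values = [
            areal_weighted_sum(SITE, r, zones, "count").value
            for r in (50, 100, 300, 500)
        ]
        assert values == sorted(values)


class TestLandUseProportion:
    def landcover_halves(self):
        return ZonalPolygonLayer(
            [
                Feature("lf", box(-1000, -1000, 0, 1000), {"class_code": "forest"}),
                Feature("lr", box(0, -1000, 1000, 1000), {"class_code": "residential"}),
            ],
            layer_kind="landcover",
        )

    def test_buffer_fully_inside_one_class(self):
        lc = ZonalPolygonLayer(
            [Feature("l", box(-1000, -1000, 1000, 1000), {"class_code": "residential"})],
            layer_kind="landcover",
        )
        out = land_use_proportion(SITE, 300.0, lc, "residential")
        assert out.value == pytest.approx(1.0, abs=1e-9)

    def test_half_plane_is_half(self):
        out = land_use_proportion(SITE, 300.0, self.landcover_halves(), "forest")
        assert out.value == pytest.approx(0.5, abs=1e-9)

    def test_absent_class_is_zero(self):
        out = land_use_proportion(SITE, 300.0, self.landcover_halves(), "wetland")
        assert out.value == 0.0

    def test_random_mosaic_matches_monte_carlo(self, rng):
        # random strip mosaic across all 12 classes
        xs = np.linspace(-400, 400, 13)
        feats = []
        classes = list(LAND_USE_CLASSES)
        rng.shuffle(classes)
        for i, cls in enumerate(classes):
            feats.append(
                Feature(f"m{i}", box(xs[i], -400, xs[i + 1], 400), {"class_code": cls})
            )
        lc = ZonalPolygonLayer(feats, layer_kind="landcover")
        r = 300.0
        for cls in classes[:4]:
            value = land_use_proportion(SITE, r, lc, cls).value
            est, sigma = mc_class_area_fraction(
                rng, SITE.x, SITE.y, r, lc, cls, n=2 * 10**5
            )
            assert abs(value - est) <= 3 * sigma + 1e-4

    def test_completeness_on_tessellating_mosaic(self, rng):
        xs = np.linspace(-400, 400, 13)
        feats = [
            Feature(f"m{i}", box(xs[i], -400, xs[i + 1], 400), {"class_code": cls})
            for i, cls in enumerate(LAND_USE_CLASSES)
        ]
        lc = ZonalPolygonLayer(feats, layer_kind="landcover")
        total = sum(
            land_use_proportion(SITE, 300.0, lc, cls).value for cls in LAND_USE_CLASSES
        )
        assert total == pytest.approx(1.0, abs=1e-6)


class TestEmissionCellsToPolygons:
    def test_sources_summed_per_pollutant(self):
        table = EmissionGridTable(
            [
                EmissionCell(0, 0, "point", "NOx", 2.0),
                EmissionCell(0, 0, "line", "NOx", 3.0),
                EmissionCell(0, 0, "area", "NOx", 5.0),
            ]
        )
        layer = emission_cells_to_polygons(table)
        assert len(layer) == 1
        assert layer.features[0].attributes["NOx"] == 10.0

    def test_corner_convention(self):
        table = EmissionGridTable([EmissionCell(0, 0, "point", "CO", 1.0)])
        layer = emission_cells_to_polygons(table)
        assert set(layer.features[0].geometry.exterior.coords) == {
            (0.0, 0.0), (1000.0, 0.0), (1000.0, 1000.0), (0.0, 1000.0),
        }

    def test_adjacent_cells_tile_without_overlap(self):
        table = EmissionGridTable(
            [
                EmissionCell(0, 0, "point", "CO", 1.0),
                EmissionCell(1000, 0, "point", "CO", 1.0),
            ]
        )
        layer = emission_cells_to_polygons(table)
        a, b = layer.geometries()
        assert a.intersection(b).area == 0.0
        assert a.touches(b)


class TestEmissionBufferSum:
    def uniform_layer(self, per_cell=9.0, half=6000.0, cell=1000.0):
        cells = []
        x = -half
        while x < half:
            y = -half
            while y < half:
                cells.append(EmissionCell(x, y, "point", "NOx", per_cell))
                y += cell
            x += cell
        return emission_cells_to_polygons(EmissionGridTable(cells, cell_size=cell))

    def test_uniform_field_closed_form(self):
        layer = self.uniform_layer()
        r = 3000.0
        out = emission_buffer_sum(SITE, r, layer, "NOx")
        expected = 9.0 * math.pi * r**2 / 1000.0**2
        assert out.value == pytest.approx(expected, rel=5e-4)

    def test_all_zero_emissions(self):
        layer = self.uniform_layer(per_cell=0.0, half=2000.0)
        assert emission_buffer_sum(SITE, 3000.0, layer, "NOx").value == 0.0

    def test_single_cell_inside_buffer(self):
        layer = emission_cells_to_polygons(
            EmissionGridTable([EmissionCell(-500, -500, "point", "NOx", 7.5)])
        )
        out = emission_buffer_sum(SITE, 3000.0, layer, "NOx")
        assert out.value == pytest.approx(7.5)

    def test_unknown_pollutant(self):
        layer = self.uniform_layer(half=2000.0)
        with pytest.raises(ConfigurationError):
            emission_buffer_sum(SITE, 3000.0, layer, "O3")
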