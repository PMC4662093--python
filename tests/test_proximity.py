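import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely import affinity
from shapely.geometry import LineString, Point, Polygon, box

from geocov.errors import GeocovError
from geocov.model import (
    Feature,
    MonitoringSite,
    PointFeatureLayer,
    RoadClassScheme,
    RoadSegment,
    ROAD_TYPES,
    WidthTable,
    ZonalPolygonLayer,
)
from geocov.proximity import (
    assign_width,
    classify_road,
    classify_urban,
    derive_border_line,
    filter_major_ports,
    nearest_distance,
    road_class_share,
)
from oracles import densified_min_distance


def seg(geometry, road_type="district_road", lanes=2, speed=60.0, highway=False, sid="s"):
    return RoadSegment(sid, geometry, road_type, lanes, speed, highway)


class TestNearestDistance:
    def test_perpendicular_foot(self):
        site = MonitoringSite("a", 5.0, 3.0)
        res = nearest_distance(site, [LineString([(0, 0), (10, 0)])])
        assert res.distance == pytest.approx(3.0)

    def test_site_on_feature_is_zero(self):
        site = MonitoringSite("a", 5.0, 0.0)
        res = nearest_distance(site, [LineString([(0, 0), (10, 0)])])
        assert res.distance == 0.0

    def test_inside_polygon_is_zero(self):
        site = MonitoringSite("a", 5.0, 5.0)
        res = nearest_distance(site, [box(0, 0, 10, 10)])
        assert res.distance == 0.0

    def test_empty_layer_is_missing(self, caplog):
        site = MonitoringSite("a", 0.0, 0.0)
        with caplog.at_level("WARNING"):
            res = nearest_distance(site, [], target="MR1")
        assert res.is_missing
        assert res.nearest_feature_id is None

    def test_matches_densification_oracle(self, rng):
        # 100 random segments in a 200 m box, 1 cm densification, 1 cm agreement
        lines = []
        for _ in range(100):
            x1, y1, x2, y2 = rng.uniform(0, 200, 4)
            lines.append(LineString([(x1, y1), (x2, y2)]))
        site = MonitoringSite("a", float(rng.uniform(0, 200)), float(rng.uniform(0, 200)))
        res = nearest_distance(site, lines)
        oracle = densified_min_distance(site.x, site.y, lines, step=0.01)
        assert abs(res.distance - oracle) <= 0.01

    def test_tie_breaks_to_lowest_feature_id(self):
        site = MonitoringSite("a", 0.0, 0.0)
        feats = [
            ("b_right", LineString([(5, -10), (5, 10)])),
            ("a_left", LineString([(-5, -10), (-5, 10)])),
        ]
        res = nearest_distance(site, feats)
        assert res.nearest_feature_id == "a_left"

    def test_adding_features_never_increases_distance(self, rng):
        site = MonitoringSite("a", 50.0, 50.0)
        lines = [
            LineString(rng.uniform(0, 100, (2, 2))) for _ in range(20)
        ]
        prev = math.inf
        for k in range(1, 21):
            d = nearest_distance(site, lines[:k]).distance
            assert d <= prev + 1e-12
            prev = d

    def test_rigid_motion_invariance_and_scaling(self, rng):
        lines = [LineString(rng.uniform(0, 100, (2, 2))) for _ in range(5)]
        site = MonitoringSite("a", 20.0, 30.0)
        d0 = nearest_distance(site, lines).distance
        # rotate + translate everything coherently
        moved = [
            affinity.translate(affinity.rotate(l, 37.0, origin=(0, 0)), 1e4, -2e3)
            for l in lines
        ]
        p = affinity.translate(affinity.rotate(Point(site.x, site.y), 37.0, origin=(0, 0)), 1e4, -2e3)
        d1 = nearest_distance(MonitoringSite("a", p.x, p.y), moved).distance
        assert d1 == pytest.approx(d0, rel=1e-9)
        # uniform scaling scales distances linearly
        scaled = [affinity.scale(l, 3.0, 3.0, origin=(0, 0)) for l in lines]
        d3 = nearest_distance(MonitoringSite("a", site.x * 3, site.y * 3), scaled).distance
        assert d3 == pytest.approx(3.0 * d0, rel=1e-9)


class TestRoadClassShare:
    def test_mr1_share_from_national_totals(self):
        assert road_class_share(8128.0, 90816.0) == 8.95

    def test_mr2_share_from_national_totals(self):
        assert road_class_share(12194.0, 90816.0) == 13.43

    def test_bad_total(self):
        with pytest.raises(GeocovError):
            road_class_share(1.0, 0.0)


class TestClassifyRoad:
    def test_national_highway_is_mr1_and_mr2(self):
        s = seg(LineString([(0, 0), (1, 0)]), road_type="national_highway", lanes=4)
        assert classify_road(s) == {"ALL", "MR1", "MR2"}

    def test_wide_local_road_is_mr2_only(self):
        s = seg(LineString([(0, 0), (1, 0)]), road_type="district_road", lanes=8)
        assert classify_road(s) == {"ALL", "MR2"}

    def test_narrow_local_road_is_all_only(self):
        s = seg(LineString([(0, 0), (1, 0)]), road_type="district_road", lanes=2)
        assert classify_road(s) == {"ALL"}

    def test_exactly_threshold_lanes_not_mr2(self):
        s = seg(LineString([(0, 0), (1, 0)]), road_type="district_road", lanes=6)
        assert "MR2" not in classify_road(s)

    @given(
        road_type=st.sampled_from(ROAD_TYPES),
        lanes=st.integers(min_value=1, max_value=12),
        threshold=st.integers(min_value=1, max_value=10),
    )
    @settings(max_examples=200, deadline=None)
    def test_nesting_property(self, road_type, lanes, threshold):
        s = seg(LineString([(0, 0), (1, 0)]), road_type=road_type, lanes=lanes)
        classes = classify_road(s, RoadClassScheme(mr2_lane_threshold=threshold))
        assert "ALL" in classes
        if "MR1" in classes:
            assert "MR2" in classes
        assert classes <= {"ALL", "MR1", "MR2"}


class TestClassifyUrban:
    def urbanized(self):
        return ZonalPolygonLayer(
            [Feature("u", box(0, 0, 100, 100), {})], layer_kind="urbanized_area"
        )

    def test_inside(self):
        s = seg(LineString([(10, 10), (20, 20)]))
        assert classify_urban(s, self.urbanized()) is True

    def test_crossing_edge(self):
        s = seg(LineString([(90, 50), (110, 50)]))
        assert classify_urban(s, self.urbanized()) is True

    def test_far_outside(self):
        s = seg(LineString([(1100, 50), (1200, 50)]))
        assert classify_urban(s, self.urbanized()) is False


class TestAssignWidth:
    def test_lookup_matches_table(self):
        t = WidthTable.default()
        s = seg(LineString([(0, 0), (1, 0)]), speed=100.0, highway=True)
        assert assign_width(s, False, t) == 3.6

    def test_urban_nonhighway(self):
        t = WidthTable.default()
        s = seg(LineString([(0, 0), (1, 0)]), speed=60.0)
        assert assign_width(s, True, t) == 3.25

    def test_uncovered_speed_raises(self):
        t = WidthTable.default()
        s = seg(LineString([(0, 0), (1, 0)]), speed=200.0)
        with pytest.raises(Exception, match="200"):
            assign_width(s, False, t)


class TestFilterMajorPorts:
    def ports(self, counts):
        return PointFeatureLayer(
            [
                Feature(f"p{i}", Point(i, 0), {"vessels_per_year": float(c)})
                for i, c in enumerate(counts)
            ],
            kind="port",
        )

    def test_strict_inequality(self):
        out = filter_major_ports(self.ports([9000, 10000, 10001]), 10000)
        assert [f.feature_id for f in out] == ["p2"]

    def test_empty_layer(self):
        out = filter_major_ports(self.ports([]), 10000)
        assert len(out) == 0

    def test_ten_of_thirty_one_synthetic_ports(self, scene):
        out = filter_major_ports(scene.bundle.depots["port"], 10000)
        assert len(scene.bundle.depots["port"]) == 31
        assert len(out) == 10

    def test_monotone_in_threshold(self, scene):
        ports = scene.bundle.depots["port"]
        sizes = [
            len(filter_major_ports(ports, t))
            for t in (0, 5000, 10000, 20000, 60000)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestDeriveBorderLine:
    def quadrants(self):
        return ZonalPolygonLayer(
            [
                Feature("q1", box(0, 0, 0.5, 0.5), {}),
                Feature("q2", box(0.5, 0, 1, 0.5), {}),
                Feature("q3", box(0, 0.5, 0.5, 1), {}),
                Feature("q4", box(0.5, 0.5, 1, 1), {}),
            ],
            layer_kind="admin_district",
        )

    def test_unit_square_top_edge(self):
        border = derive_border_line(self.quadrants(), northern_fraction=0.25)
        assert border.length == pytest.approx(1.0)
        xs, ys = [], []
        geoms = getattr(border, "geoms", [border])
        for g in geoms:
            for x, y in g.coords:
                xs.append(x)
                ys.append(y)
        assert all(y == pytest.approx(1.0) for y in ys)

    def test_single_rectangle_top_portion(self):
        layer = ZonalPolygonLayer(
            [Feature("r", box(0, 0, 10, 2), {})], layer_kind="admin_district"
        )
        border = derive_border_line(layer, northern_fraction=0.25)
        # only the top edge (y=2) has midpoint in the top quarter of y-extent
        assert border.length == pytest.approx(10.0)

    def test_two_islands_uses_larger(self, caplog):
        layer = ZonalPolygonLayer(
            [
                Feature("big", box(0, 0, 10, 10), {}),
                Feature("small", box(100, 0, 102, 2), {}),
            ],
            layer_kind="admin_district",
        )
        with caplog.at_level("WARNING"):
            border = derive_border_line(layer, northern_fraction=0.25)
        minx, _, maxx, _ = border.bounds
        assert maxx <= 10.0  # entirely on the big island
        assert any("disjoint" in r.message for r in caplog.records)

    def test_empty_layer_raises(self):
        layer = ZonalPolygonLayer([], layer_kind="admin_district")
        with pytest.raises(GeocovError):
            derive_border_line(layer)
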