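"""Fix ingestion, segmentation, kernel density, grading and zone logic."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

import grazemap as gm
from grazemap.trajectory import FixIngest, Zone, ZoneMap, silverman_bandwidth


def _planar_traj(xy, t0="2020-08-01T06:00:00", dt=120, animal="a1"):
    xy = np.asarray(xy, float)
    times = np.datetime64(t0, "ns") + (np.arange(len(xy)) * dt * 10**9).astype(
        "timedelta64[ns]"
    )
    return gm.Trajectory(animal, times, xy[:, 0], xy[:, 1])


class TestReadFixes:
    def test_malformed_rows_dropped_and_counted(self, tmp_path):
        p = tmp_path / "f.csv"
        p.write_text(
            "animal_id,timestamp,lon,lat\n"
            "a1,2020-08-01T06:00:00,107.60,39.00\n"
            "a1,2020-08-01T06:02:00,107.601,39.001\n"
            "a1,not-a-time,107.602,39.002\n"
            "a1,2020-08-01T06:04:00,107.602,39.002\n"
        )
        res = gm.read_fixes(p)
        assert res.n_dropped == 1
        assert len(res.trajectories) == 1
        assert len(res.trajectories[0]) == 3

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("animal_id,timestamp,lon,lat\n")
        res = gm.read_fixes(p)
        assert res.trajectories == [] and res.n_dropped == 0

    def test_two_animals_interleaved(self, tmp_path):
        p = tmp_path / "two.csv"
        rows = ["animal_id,timestamp,x,y"]
        for i in range(3):
            rows.append(f"a2,2020-08-01T06:{2 * i:02d}:00,{i},0")
            rows.append(f"a1,2020-08-01T06:{2 * i + 1:02d}:00,{i},1")
        p.write_text("\n".join(rows) + "\n")
        res = gm.read_fixes(p)
        assert len(res.trajectories) == 2
        for traj in res.trajectories:
            assert np.all(np.diff(traj.times).astype(int) > 0)

    def test_duplicate_timestamps_collapse_to_first(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "animal_id,timestamp,x,y\n"
            "a1,2020-08-01T06:00:00,0,0\n"
            "a1,2020-08-01T06:00:00,99,99\n"
            "a1,2020-08-01T06:02:00,1,1\n"
        )
        res = gm.read_fixes(p)
        assert res.n_duplicates == 1
        assert res.trajectories[0].x[0] == 0

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("animal_id,lon,lat\na1,107.6,39.0\n")
        with pytest.raises(ValueError, match="timestamp"):
            gm.read_fixes(p)

    def test_gpx_dialect(self, tmp_path):
        p = tmp_path / "t.gpx"
        p.write_text(
            '<?xml version="1.0"?>\n'
            '<gpx xmlns="http://www.topografix.com/GPX/1/1" version="1.1">'
            "<trk><name>a1</name><trkseg>"
            '<trkpt lon="107.600" lat="39.000"><time>2020-08-01T06:00:00Z</time></trkpt>'
            '<trkpt lon="107.601" lat="39.001"><time>2020-08-01T06:02:00Z</time></trkpt>'
            "</trkseg></trk></gpx>"
        )
        res = gm.read_fixes(p, dialect="gpx")
        assert len(res.trajectories) == 1
        assert len(res.trajectories[0]) == 2


class TestSegmentize:
    def test_zero_length_segment(self):
        segs, _ = gm.segmentize(_planar_traj([(5, 5), (5, 5), (6, 5)]))
        assert segs[0].length == 0.0

    def test_one_degree_latitude_is_speed_filtered(self):
        times = np.array(
            ["2020-08-01T06:00:00", "2020-08-01T06:02:00"], dtype="datetime64[ns]"
        )
        lat = np.array([39.0, 40.0])
        lon = np.array([107.6, 107.6])
        x, y = gm.geodata.lonlat_to_planar(lon, lat)
        traj = gm.Trajectory("a1", times, x, y, lon, lat)
        # haversine length of 1 degree of latitude
        assert gm.haversine(107.6, 39.0, 107.6, 40.0) == pytest.approx(111_195, rel=1e-3)
        segs, n_glitch = gm.segmentize(traj)
        assert segs == [] and n_glitch == 1

    def test_full_day_durations_telescope(self, sim_day):
        traj, _ = sim_day
        segs, _ = gm.segmentize(traj)
        assert len(segs) == 360
        assert sum(s.duration for s in segs) == pytest.approx(43_200)

    def test_fewer_than_two_fixes(self):
        segs, n = gm.segmentize(_planar_traj([(0, 0)]))
        assert segs == [] and n == 0


class TestKernelDensity:
    def test_single_fix_max_at_containing_cell(self, toy_grid):
        dens = gm.kernel_density(np.array([[32.0, 97.0]]), 10.0, toy_grid)
        r, c = np.unravel_index(np.argmax(dens.values), dens.values.shape)
        assert (r, c) == toy_grid.cell_of(32.0, 97.0)

    def test_integrates_to_fix_count(self, toy_grid):
        rng = np.random.default_rng(1)
        pts = rng.uniform(40, 90, size=(50, 2))
        dens = gm.kernel_density(pts, 5.0, toy_grid)
        assert dens.values.sum() * toy_grid.cell_area == pytest.approx(50, rel=1e-9)

    def test_two_separated_clusters_two_maxima(self, toy_grid):
        pts = np.vstack(
            [
                np.random.default_rng(0).normal((30, 30), 2, (40, 2)),
                np.random.default_rng(1).normal((100, 100), 2, (40, 2)),
            ]
        )
        dens = gm.kernel_density(pts, 4.0, toy_grid)
        v = dens.values
        assert v[toy_grid.cell_of(30, 30)] > 0 and v[toy_grid.cell_of(100, 100)] > 0
        lo = v[toy_grid.cell_of(65, 65)]
        assert v[toy_grid.cell_of(30, 30)] > 10 * lo

    def test_matches_brute_force_oracle(self):
        """Truncated-Gaussian brute force, written independently."""
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 500, size=(200, 2))
        grid = gm.GridSpec(origin=(0.0, 500.0), extent=(500.0, 500.0), cell_size=10.0)
        h = 25.0
        dens = gm.kernel_density(pts, h, grid)

        nrows, ncols = grid.shape
        oracle = np.zeros((nrows, ncols))
        for r in range(nrows):
            for c in range(ncols):
                cx = 0.0 + (c + 0.5) * 10.0
                cy = 500.0 - (r + 0.5) * 10.0
                acc = 0.0
                for px, py in pts:
                    d2 = (cx - px) ** 2 + (cy - py) ** 2
                    if d2 <= (4 * h) ** 2:
                        acc += np.exp(-0.5 * d2 / h**2) / (2 * np.pi * h**2)
                oracle[r, c] = acc
        oracle *= len(pts) / (oracle.sum() * grid.cell_area)
        np.testing.assert_allclose(dens.values, oracle, atol=1e-9)

    def test_bad_bandwidth_rejected(self, toy_grid):
        with pytest.raises(ValueError, match="bandwidth"):
            gm.kernel_density(np.array([[1.0, 1.0]]), -1.0, toy_grid)

    def test_silverman_default_is_scale_aware(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 10, 100), rng.normal(0, 10, 100)
        assert silverman_bandwidth(10 * x, 10 * y) == pytest.approx(
            10 * silverman_bandwidth(x, y), rel=1e-9
        )


class TestGradeDensity:
    def _density(self, vals, cell=1.0):
        vals = np.asarray(vals, float)
        return gm.Raster(vals, (0.0, vals.shape[0] * cell), cell, band_meaning="density")

    def test_constant_density_single_grade(self):
        g = gm.grade_density(self._density(np.full((4, 4), 3.0)))
        assert len(np.unique(g.values)) == 1

    def test_all_zero_is_grade_one(self):
        g = gm.grade_density(self._density(np.zeros((3, 3))))
        assert np.all(g.values == 1)

    def test_five_grades_on_rich_input(self):
        vals = np.arange(1, 101, dtype=float).reshape(10, 10)
        g = gm.grade_density(self._density(vals))
        assert set(np.unique(g.values)) == {1, 2, 3, 4, 5}

    @pytest.mark.parametrize("scheme", ["quantile", "jenks", "equal_interval"])
    def test_grading_is_monotone(self, scheme):
        rng = np.random.default_rng(9)
        vals = rng.exponential(1.0, size=(10, 10))
        g = gm.grade_density(self._density(vals), scheme)
        order = np.argsort(vals.ravel())
        grades_sorted = g.values.ravel()[order]
        assert np.all(np.diff(grades_sorted) >= 0)

    def test_quantile_class_counts_near_equal(self):
        # order-statistics oracle: 100 distinct values -> 20 per class +- 1
        vals = np.random.default_rng(2).permutation(np.linspace(1, 2, 100)).reshape(10, 10)
        g = gm.grade_density(self._density(vals), "quantile")
        counts = [int((g.values == k).sum()) for k in range(1, 6)]
        assert all(abs(c - 20) <= 1 for c in counts)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            gm.grade_density(self._density(np.ones((3, 3))), "fancy")


class TestZones:
    def _zone_setup(self):
        """Dense stationary cluster at the pen, dense cluster at water, sparse track."""
        rng = np.random.default_rng(4)
        pen = (20.0, 110.0)
        water = (100.0, 30.0)
        rest_xy = pen + rng.normal(0, 1.0, (60, 2)) * 0.5
        drink_xy = water + rng.normal(0, 1.0, (25, 2))
        # moving fixes: a line across the middle, 50 m apart -> low density
        track_xy = np.column_stack([np.linspace(5, 125, 20), np.full(20, 70.0)])
        xy = np.vstack([rest_xy, drink_xy, track_xy])
        traj = _planar_traj(xy)
        grid = gm.GridSpec(origin=(0.0, 130.0), extent=(130.0, 130.0), cell_size=5.0)
        dens = gm.kernel_density(xy, 3.0, grid)
        grades = gm.grade_density(dens)
        return traj, grades, pen, water

    def test_water_cluster_classified_drinking(self):
        traj, grades, pen, water = self._zone_setup()
        zones = gm.classify_zones(grades, [traj], water_point=water)
        classes = {z.zone_class for z in zones.clusters}
        assert "drinking" in classes
        for z in zones.clusters:
            if z.polygon.covers(shapely.Point(*water)):
                assert z.zone_class == "drinking"

    def test_stationary_cluster_classified_rest(self):
        traj, grades, pen, water = self._zone_setup()
        zones = gm.classify_zones(grades, [traj], water_point=water)
        rest_polys = zones.polygons("rest")
        assert rest_polys and any(p.covers(shapely.Point(*pen)) for p in rest_polys)

    def test_overrides_win_over_rules(self):
        traj, grades, pen, water = self._zone_setup()
        override = box(water[0] - 10, water[1] - 10, water[0] + 10, water[1] + 10)
        zones = gm.classify_zones(
            grades, [traj], water_point=water, overrides=[(override, "grazing")]
        )
        for z in zones.clusters:
            if z.polygon.intersects(override):
                assert z.zone_class == "grazing"

    def test_planted_rest_zone_recovered(self, sim_config, sim_day):
        """Simulated day: the planted rest polygon overlaps a recovered rest
        cluster by >= 80% of its fix-occupied area."""
        traj, truth = sim_day
        grid = sim_config.grid_spec(cell_size=13.0)
        dens = gm.kernel_density(np.column_stack([traj.x, traj.y]), 10.0, grid)
        grades = gm.grade_density(dens)
        zones = gm.classify_zones(grades, [traj], water_point=sim_config.water_location)
        rest_truth = [p for p, c in truth.zone_polygons if c == "rest"][0]
        rest_polys = zones.polygons("rest")
        assert rest_polys
        recovered = shapely.unary_union(rest_polys)
        # compare on the fixes: the recovered rest zone captures the fixes
        # that dwell inside the planted polygon
        in_truth = shapely.contains_xy(rest_truth, traj.x, traj.y)
        in_found = shapely.contains_xy(recovered, traj.x, traj.y)
        overlap = (in_truth & in_found).sum() / in_truth.sum()
        assert overlap >= 0.8

    def test_exclude_all_and_none(self):
        traj = _planar_traj([(1, 1), (2, 1), (3, 1)])
        zone_all = ZoneMap(
            density=None, grades=None,
            clusters=[Zone(box(0, 0, 10, 10), "rest", 1)],
        )
        out, n = gm.exclude_zones(traj, zone_all)
        assert len(out) == 0 and n == 3
        zone_none = ZoneMap(
            density=None, grades=None,
            clusters=[Zone(box(50, 50, 60, 60), "drinking", 1)],
        )
        out, n = gm.exclude_zones(traj, zone_none)
        assert len(out) == 3 and n == 0

    def test_exclusion_gap_never_bridged(self):
        # 7 fixes on a line; the middle 3 sit inside a rest zone
        xy = [(i * 10.0, 5.0) for i in range(7)]
        traj = _planar_traj(xy)
        zones = ZoneMap(
            density=None, grades=None,
            clusters=[Zone(box(15, 0, 45, 10), "rest", 1)],
        )
        out, n = gm.exclude_zones(traj, zones)
        assert n == 3
        segs, _ = gm.segmentize(out)
        # two sub-runs of 2 fixes each -> 1 segment per run, none spanning the gap
        assert len(segs) == 2
        assert max(s.duration for s in segs) == 120

    def test_exclude_zones_idempotent(self, sim_day):
        traj, truth = sim_day
        zones = ZoneMap(
            density=None, grades=None,
            clusters=[Zone(p, c, i) for i, (p, c) in enumerate(truth.zone_polygons)],
        )
        once, n1 = gm.exclude_zones(traj, zones)
        twice, n2 = gm.exclude_zones(once, zones)
        assert n2 == 0
        np.testing.assert_array_equal(once.x, twice.x)
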