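"""Hotspot clustering, fire-day assignment, and gridded fire areas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from smokecast import fire


def pts(coords):
    return pd.DataFrame(
        {"id": range(len(coords)), "lon": [c[0] for c in coords], "lat": [c[1] for c in coords]}
    )


REF = (151.05, -33.89)
KM_LON = 111.195 * np.cos(np.radians(REF[1]))  # km per degree longitude here


class TestFireDay:
    @pytest.mark.parametrize(
        "ts, expected",
        [
            ("2019-04-28 13:30", "2019-04-28"),  # afternoon overpass
            ("2019-04-29 01:00", "2019-04-28"),  # pre-7am night overpass -> prior day
            ("2019-04-29 12:00", "2019-04-29"),  # half-open window boundary
            ("2019-04-29 06:59", "2019-04-28"),
            ("2019-04-29 07:00", "2019-04-29"),  # morning gap stays on its date
            ("2019-04-28 23:59", "2019-04-28"),
        ],
    )
    def test_midday_to_midday_assignment(self, ts, expected):
        assert str(fire.assign_fire_day(ts)) == expected


class TestBuffer:
    def test_zero_distance_inside(self):
        assert fire.within_buffer(REF[0], REF[1], REF)

    def test_149km_in_151km_out(self):
        east_149 = (REF[0] + 149.0 / KM_LON, REF[1])
        east_151 = (REF[0] + 151.0 / KM_LON, REF[1])
        assert fire.within_buffer(*east_149, REF)
        assert not fire.within_buffer(*east_151, REF)

    def test_antipode_outside(self):
        assert not fire.within_buffer(REF[0] - 180.0, -REF[1], REF)


class TestClustering:
    def test_three_close_points_one_cluster(self):
        p = pts([(151.0, -33.9), (151.0 + 1 / KM_LON, -33.9), (151.0, -33.9 + 1 / 111.195)])
        clusters = fire.cluster_hotspots(p)
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_chain_linkage_merges(self):
        # 0, 4, 8 km along a line: pairwise 0-8 km exceeds 5 km but chains
        p = pts([(151.0 + d / KM_LON, -33.9) for d in (0.0, 4.0, 8.0)])
        clusters = fire.cluster_hotspots(p)
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_distant_points_separate(self):
        p = pts([(151.0, -33.9), (151.0 + 10.0 / KM_LON, -33.9)])
        assert sorted(c.size for c in fire.cluster_hotspots(p)) == [1, 1]

    def test_empty_input(self):
        assert fire.cluster_hotspots(pts([])) == []

    def test_matches_brute_force_components(self):
        # independent oracle: connected components of the <=5 km graph
        import networkx as nx

        rng = np.random.default_rng(5)
        lon = REF[0] + rng.uniform(-0.3, 0.3, 60)
        lat = REF[1] + rng.uniform(-0.3, 0.3, 60)
        p = pd.DataFrame({"id": range(60), "lon": lon, "lat": lat})
        got = {c.member_ids for c in fire.cluster_hotspots(p)}
        g = nx.Graph()
        g.add_nodes_from(range(60))
        for i in range(60):
            for j in range(i + 1, 60):
                if fire.haversine_km(lon[i], lat[i], lon[j], lat[j]) <= 5.0:
                    g.add_edge(i, j)
        want = {frozenset(c) for c in nx.connected_components(g)}
        assert got == want

    @given(perm_seed=st.integers(0, 10_000))
    @hyp_settings(max_examples=20, deadline=None)
    def test_order_invariance(self, perm_seed):
        rng = np.random.default_rng(17)
        p = pd.DataFrame(
            {
                "id": range(40),
                "lon": REF[0] + rng.uniform(-0.2, 0.2, 40),
                "lat": REF[1] + rng.uniform(-0.2, 0.2, 40),
            }
        )
        shuffled = p.sample(frac=1.0, random_state=perm_seed).reset_index(drop=True)
        assert fire.cluster_hotspots(p) == fire.cluster_hotspots(shuffled)


class TestActiveRule:
    def test_isolated_points_inactive(self):
        sizes = [fire.Cluster(frozenset([1])), fire.Cluster(frozenset([2, 3]))]
        assert not fire.is_active_day(sizes)

    def test_triple_cluster_active(self):
        assert fire.is_active_day([fire.Cluster(frozenset([1, 2, 3]))])

    def test_empty_inactive(self):
        assert not fire.is_active_day([])


class TestRasterize:
    def test_point_at_cell_centre_one_cell(self):
        g = fire.GridSpec()
        assert len(fire.rasterize_footprints([[250.0, 250.0]], g)) == 1

    def test_point_on_corner_four_cells(self):
        # oracle: shapely polygon intersection over a candidate neighbourhood
        from shapely.geometry import box

        g = fire.GridSpec()
        for xy in ([0.0, 0.0], [500.0, 1000.0], [130.0, 220.0], [312.5, 250.0]):
            got = fire.rasterize_footprints([xy], g)
            fp = box(xy[0] - 187.5, xy[1] - 187.5, xy[0] + 187.5, xy[1] + 187.5)
            want = set()
            for i in range(-2, 4):
                for j in range(-2, 4):
                    cell = box(i * 500.0, j * 500.0, (i + 1) * 500.0, (j + 1) * 500.0)
                    if fp.intersection(cell).area > 0:
                        want.add((i, j))
            assert got == want
        assert len(fire.rasterize_footprints([[0.0, 0.0]], g)) == 4

    def test_day_night_double_capture_collapses(self):
        g = fire.GridSpec()
        once = fire.rasterize_footprints([[250.0, 250.0]], g)
        twice = fire.rasterize_footprints([[250.0, 250.0], [250.0, 250.0]], g)
        assert once == twice

    def test_point_mode_single_cell(self):
        g = fire.GridSpec()
        assert fire.rasterize_footprints([[499.0, 1.0]], g, mode="point") == {(0, 0)}


class TestAreas:
    def test_empty_zero(self):
        assert fire.daily_fire_area(np.empty((0, 2)), fire.GridSpec()) == 0.0

    def test_single_cell_is_25_ha(self):
        assert fire.daily_fire_area(np.array([[250.0, 250.0]]), fire.GridSpec()) == 25.0

    def test_n_disjoint_points_25n(self):
        xy = np.array([[250.0 + 5000.0 * k, 250.0] for k in range(7)])
        assert fire.daily_fire_area(xy, fire.GridSpec()) == 25.0 * 7

    def test_monotone_in_added_hotspots(self):
        g = fire.GridSpec()
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 5000, size=(30, 2))
        areas = [fire.daily_fire_area(xy[:k], g) for k in range(1, 31)]
        assert all(a2 >= a1 for a1, a2 in zip(areas, areas[1:]))


class TestSectors:
    @pytest.mark.parametrize(
        "bearing, sector",
        [
            (270.0, "west"),
            (0.0, "north"),
            (90.0, "none"),
            (180.0, "south"),
            (225.0, "west"),
            (315.0, "north"),
            (135.0, "south"),
            (44.9, "north"),
            (45.0, "none"),
        ],
    )
    def test_sector_of(self, bearing, sector):
        assert fire.sector_of(bearing) == sector

    def test_all_west_points(self):
        g = fire.GridSpec.for_buffer()
        p = pts([(REF[0] - d / KM_LON, REF[1]) for d in (30.0, 31.0, 60.0)])
        fa = fire.sector_areas(p, REF, g)
        assert fa.area_west == fa.area_total > 0
        assert fa.area_south == fa.area_north == 0.0

    def test_split_sectors_sum_to_total(self):
        g = fire.GridSpec.for_buffer()
        west = [(REF[0] - 40.0 / KM_LON, REF[1])]
        north = [(REF[0], REF[1] + 40.0 / 111.195)]
        fa = fire.sector_areas(pts(west + north), REF, g)
        assert fa.area_west + fa.area_north == fa.area_total
        assert fa.area_south == 0.0

    def test_east_counts_only_toward_total(self):
        g = fire.GridSpec.for_buffer()
        p = pts([(REF[0] + 40.0 / KM_LON, REF[1])])
        fa = fire.sector_areas(p, REF, g)
        assert fa.area_total > 0
        assert fa.area_west == fa.area_south == fa.area_north == 0.0


class TestFireDayTable:
    def test_from_synthetic_hotspots(self, small_dataset):
        ds = small_dataset
        table = fire.fire_day_table(ds.hotspots, ds.config.reference_point)
        day_types = ds.hotspots.attrs["day_types"]
        by_day = table.set_index("fire_day")
        for day, kind in day_types.items():
            if kind == "active":
                assert bool(by_day.loc[day, "active"])
                assert by_day.loc[day, "max_cluster_size"] >= 3
            elif kind == "isolated":
                assert day not in by_day.index or not by_day.loc[day, "active"]

    def test_decoys_filtered_by_buffer(self):
        from smokecast.synthetic import SimulationConfig, generate_hotspots

        cfg = SimulationConfig(n_days=30, seed=1, decoys=True)
        hs = generate_hotspots(cfg)
        d = fire.haversine_km(cfg.reference_point[0], cfg.reference_point[1], hs["lon"], hs["lat"])
        assert (d > 150.0).any()
        table = fire.fire_day_table(hs, cfg.reference_point)
        assert table["n_hotspots"].sum() == (d <= 150.0).sum()
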