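"""Occurrence filtering, thinning, background sampling, AOO, time slicing."""

import numpy as np
import pandas as pd
import pytest

from invasdm.geo import haversine_km
from invasdm.occurrences import (OccurrenceSet, area_of_occupancy,
                                 build_background, downsample_grid,
                                 filter_records, time_slice)
from invasdm.raster import RasterStack


def make_occ(lon, lat, year=None, precision=0.01, ids=None):
    n = len(lon)
    return OccurrenceSet(pd.DataFrame({
        "id": ids or [f"r{i}" for i in range(n)],
        "longitude": lon, "latitude": lat,
        "year": year if year is not None else [2000] * n,
        "precision": precision if np.ndim(precision) else [precision] * n,
        "source": "test", "is_county_centroid": False}))


class TestFilterRecords:
    def test_exact_coordinate_duplicates_collapse_to_one(self):
        occ = make_occ([-100.0, -100.0, -99.0], [35.0, 35.0, 35.0])
        out = filter_records(occ, drop_outliers=False)
        assert len(out) == 2

    def test_precision_rule_drops_coarse_keeps_fine(self):
        occ = make_occ([-100.0, -99.0], [35.0, 35.0], precision=[0.5, 0.01])
        out = filter_records(occ, drop_outliers=False)
        assert list(out.records["id"]) == ["r1"]

    def test_distant_outlier_removed_by_nn_rule(self, rng):
        # 100 clustered records plus one ~5,000 km away
        lon = np.append(-100 + rng.uniform(-1, 1, 100), -50.0)
        lat = np.append(35 + rng.uniform(-1, 1, 100), 30.0)
        occ = make_occ(lon, lat)
        d = haversine_km(-50.0, 30.0, -100.0, 35.0)
        assert d > 4000
        out = filter_records(occ)
        assert "r100" not in set(out.records["id"])
        assert len(out) == 100

    def test_result_is_order_independent(self, rng):
        lon = -100 + rng.uniform(-2, 2, 50)
        lat = 35 + rng.uniform(-2, 2, 50)
        occ = make_occ(lon, lat)
        shuffled = OccurrenceSet(occ.records.sample(frac=1, random_state=1))
        a = set(filter_records(occ).records["id"])
        b = set(filter_records(shuffled).records["id"])
        assert a == b

    def test_idempotent_and_never_grows(self, rng):
        lon = -100 + rng.uniform(-2, 2, 60)
        lat = 35 + rng.uniform(-2, 2, 60)
        occ = make_occ(lon, lat)
        once = filter_records(occ)
        twice = filter_records(once)
        assert len(once) <= len(occ)
        assert list(once.records["id"]) == list(twice.records["id"])

    def test_county_centroid_override(self):
        df = pd.DataFrame({
            "id": ["a", "b"], "longitude": [-100.0, -99.0],
            "latitude": [35.0, 35.0], "year": [2000, 2000],
            "precision": [0.3, 0.3], "source": "county",
            "is_county_centroid": [True, False]})
        occ = OccurrenceSet(df)
        strict = filter_records(occ, drop_outliers=False)
        lenient = filter_records(occ, drop_outliers=False,
                                 keep_county_centroids=True)
        assert len(strict) == 0
        assert list(lenient.records["id"]) == ["a"]


class TestDownsampleGrid:
    def test_points_in_same_cell_collapse(self):
        # ~10 km apart at 35N
        occ = make_occ([-100.0, -100.11], [35.0, 35.0])
        assert len(downsample_grid(occ, cell_km=50)) == 1

    def test_points_in_distant_cells_both_kept(self):
        occ = make_occ([-100.0, -97.8], [35.0, 35.0])      # ~200 km apart
        assert len(downsample_grid(occ, cell_km=50)) == 2

    def test_output_count_equals_number_of_occupied_cells(self, rng):
        from invasdm.geo import equal_area_xy_km
        lon = -100 + rng.uniform(0, 5, 1000)
        lat = 33 + rng.uniform(0, 5, 1000)
        occ = make_occ(lon, lat)
        out = downsample_grid(occ, cell_km=50)
        x, y = equal_area_xy_km(lon, lat)
        n_cells = len({(int(np.floor(a / 50)), int(np.floor(b / 50)))
                       for a, b in zip(x, y)})
        assert len(out) == n_cells

    def test_earliest_year_retained_with_id_tiebreak(self):
        occ = make_occ([-100.0, -100.01, -100.02], [35.0, 35.0, 35.0],
                       year=[1990, 1950, 1950])
        out = downsample_grid(occ, cell_km=50)
        assert list(out.records["id"]) == ["r1"]           # 1950, smaller id

    def test_idempotent(self, rng):
        occ = make_occ(-100 + rng.uniform(0, 8, 300), 33 + rng.uniform(0, 8, 300),
                       year=rng.integers(1950, 2010, 300).tolist())
        once = downsample_grid(occ)
        twice = downsample_grid(once)
        assert once.records[["id"]].equals(twice.records[["id"]])


class TestBuildBackground:
    def test_points_fall_within_buffer_distance(self):
        stack = RasterStack(["t"], np.zeros((1, 40, 40)), -102.0, -98.0,
                            33.0, 37.0)
        occ = make_occ([-100.0], [35.0])
        bg = build_background(occ, stack, buffer_km=100, n=500, seed=1)
        d = haversine_km(bg.lon, bg.lat, -100.0, 35.0)
        # cell centres are in the buffer; jitter can add half a diagonal
        assert d.max() <= 100 + 12

    def test_area_weighting_prefers_low_latitudes(self):
        # two one-cell rows with centres at 0 and 60 degrees latitude
        stack = RasterStack(["t"], np.zeros((1, 2, 1)), -100.0, -99.0,
                            -30.0, 90.0)
        lon_c, lat_c = stack.cell_centers()
        assert np.allclose(sorted(lat_c), [0.0, 60.0])
        occ = make_occ([-99.5], [30.0])
        bg = build_background(occ, stack, buffer_km=8000, n=10_000, seed=2)
        frac_low = (bg.lat < 30).mean()
        # cos(0):cos(60) = 2:1 -> expected 2/3, binomial 99% CI half-width ~0.012
        assert abs(frac_low - 2 / 3) < 0.015

    def test_masked_cells_never_sampled(self):
        vals = np.zeros((1, 10, 10))
        vals[0, :5, :] = np.nan
        stack = RasterStack(["t"], vals, -101.0, -99.0, 34.0, 36.0)
        occ = make_occ([-100.0], [35.0])
        bg = build_background(occ, stack, buffer_km=300, n=400, seed=3)
        rows, _ = stack.lonlat_to_rowcol(bg.lon, bg.lat)
        assert (rows >= 5).all()

    def test_zero_points_requested_gives_empty_sample(self, study):
        bg = build_background(study["occ"], study["stack"], buffer_km=100,
                              n=0, seed=0)
        assert len(bg) == 0

    def test_empty_occurrences_rejected(self, study):
        empty = study["occ"].with_records(study["occ"].records.iloc[:0], "empty")
        with pytest.raises(ValueError, match="empty"):
            build_background(empty, study["stack"])


class TestAreaOfOccupancy:
    def test_colocated_records_occupy_one_cell(self):
        occ = make_occ([-100.0001, -100.0002, -100.0003], [35.0001] * 3)
        assert area_of_occupancy(occ) == 1

    def test_records_in_k_distinct_cells_count_k(self):
        d = 30 / 3600
        lon = [-100 + (i + 0.5) * d for i in range(7)]
        occ = make_occ(lon, [35.0 + 0.5 * d] * 7)
        assert area_of_occupancy(occ) == 7

    def test_matches_brute_force_cell_enumeration(self, study):
        occ = study["occ"]
        d = 30 / 3600
        brute = len({(int(np.floor((lo + 180) / d)), int(np.floor((la + 90) / d)))
                     for lo, la in zip(occ.lon, occ.lat)})
        assert area_of_occupancy(occ) == brute

    def test_monotone_in_cutoff_year(self, study):
        occ = study["occ"]
        years = np.arange(1960, 2006, 5)
        aoo = [area_of_occupancy(time_slice(occ, int(y))) for y in years]
        assert all(a <= b for a, b in zip(aoo, aoo[1:]))


class TestTimeSlice:
    def test_cutoff_before_first_year_empties_set(self):
        occ = make_occ([-100.0], [35.0], year=[1990])
        assert len(time_slice(occ, 1980)) == 0

    def test_cutoff_at_last_year_keeps_all(self):
        occ = make_occ([-100.0, -99.0], [35.0, 35.0], year=[1990, 2000])
        assert len(time_slice(occ, 2000)) == 2

    def test_counts_accumulate_arithmetically(self):
        lon = np.repeat(-100.0, 200) + np.tile(np.arange(10) * 0.1, 20)
        year = np.repeat(np.arange(1960, 1980), 10)
        occ = make_occ(lon.tolist(), [35.0] * 200, year=year.tolist())
        assert len(time_slice(occ, 1970)) == 110

    def test_missing_years_excluded(self):
        occ = make_occ([-100.0, -99.0], [35.0, 35.0], year=[np.nan, 1990])
        assert list(time_slice(occ, 2000).records["id"]) == ["r1"]
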