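"""Occurrence records and the data-preparation layer.

Presence data live in an :class:`OccurrenceSet`, a thin wrapper around a pandas
DataFrame with the columns ``id, longitude, latitude, year, precision, source,
is_county_centroid``. Operations here cover the standard pre-modelling chain
for presence-only data: duplicate/precision/outlier filtering, spatial
downsampling to an equal-area grid, latitude-weighted background-point
sampling within dissolved presence buffers, area-of-occupancy counts, and
time-slicing for sequential historical models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .geo import EARTH_RADIUS_KM, equal_area_xy_km, haversine_km
from .raster import RasterStack

__all__ = [
    "OccurrenceSet", "BackgroundSample", "filter_records", "downsample_grid",
    "build_background", "area_of_occupancy", "time_slice",
]

COLUMNS = ["id", "longitude", "latitude", "year", "precision", "source",
           "is_county_centroid"]


@dataclass
class OccurrenceSet:
    """Time-stamped presence points with precision/source metadata."""

    records: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        df = self.records.copy()
        for col in COLUMNS:
            if col not in df.columns:
                df[col] = {"id": "", "source": "unknown"}.get(col, np.nan)
                if col == "is_county_centroid":
                    df[col] = False
                if col == "id":
                    df[col] = [f"r{i}" for i in range(len(df))]
        df = df[COLUMNS + [c for c in df.columns if c not in COLUMNS]]
        if df["id"].duplicated().any():
            raise ValueError("occurrence ids must be unique")
        lon = df["longitude"].to_numpy(float)
        lat = df["latitude"].to_numpy(float)
        if np.any((lon < -180) | (lon > 180)) or np.any((lat < -90) | (lat > 90)):
            raise ValueError("coordinates outside valid lon/lat bounds")
        yr = df["year"].to_numpy(float)
        if np.any(yr[~np.isnan(yr)] < 1800):
            raise ValueError("years before 1800 are not credible records")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records["longitude"].to_numpy(float)

    @property
    def lat(self) -> np.ndarray:
        return self.records["latitude"].to_numpy(float)

    @property
    def year(self) -> np.ndarray:
        return self.records["year"].to_numpy(float)

    def with_records(self, df: pd.DataFrame, note: str) -> "OccurrenceSet":
        return OccurrenceSet(df.reset_index(drop=True), self.provenance + [note])

    def to_csv(self, path) -> None:
        out = self.records.rename(columns={"precision": "coordinate_precision_deg"})
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OccurrenceSet":
        df = pd.read_csv(path)
        df = df.rename(columns={"coordinate_precision_deg": "precision"})
        return cls(df)


@dataclass
class BackgroundSample:
    """Background (pseudo-absence) points with their sampling context."""

    points: pd.DataFrame          # columns: longitude, latitude
    buffer_km: float
    weights_note: str = "cell area (cos latitude)"

    @property
    def lon(self) -> np.ndarray:
        return self.points["longitude"].to_numpy(float)

    @property
    def lat(self) -> np.ndarray:
        return self.points["latitude"].to_numpy(float)

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# filtering

def filter_records(raw: OccurrenceSet, precision_max: float = 0.1,
                   outlier_nn_quantile: float = 0.99,
                   outlier_factor: float = 10.0,
                   drop_outliers: bool = True,
                   keep_county_centroids: bool = False) -> OccurrenceSet:
    """Remove duplicates, low-precision records and geographic outliers.

    Records are dropped when (a) they duplicate another record's exact
    coordinates, (b) their coordinate precision is ``precision_max`` degrees or
    coarser, or (c) their nearest-neighbour distance exceeds
    ``outlier_factor`` times the ``outlier_nn_quantile`` quantile of all
    nearest-neighbour distances. County-centroid records are ordinary records
    whose precision is the county's nominal radius; ``keep_county_centroids``
    exempts them from the precision rule.

    The result is order-independent: duplicate resolution keeps the smallest id.
    """
    df = raw.records.sort_values("id", kind="stable")
    df = df.drop_duplicates(subset=["longitude", "latitude"], keep="first")

    prec = df["precision"].to_numpy(float)
    ok = np.isnan(prec) | (prec < precision_max)
    if keep_county_centroids:
        ok |= df["is_county_centroid"].to_numpy(bool)
    df = df[ok]

    n_out = 0
    if drop_outliers and len(df) >= 3:
        from scipy.spatial import cKDTree
        # equal-area projected coordinates make Euclidean NN distances ~km
        x, y = equal_area_xy_km(df["longitude"].to_numpy(float),
                                df["latitude"].to_numpy(float))
        tree = cKDTree(np.column_stack([x, y]))
        d, _ = tree.query(np.column_stack([x, y]), k=2)
        nn = d[:, 1]
        cut = outlier_factor * np.quantile(nn, outlier_nn_quantile)
        keep = nn <= cut
        n_out = int((~keep).sum())
        df = df[keep]

    note = (f"filter: precision<{precision_max} deg, duplicates dropped, "
            f"{n_out} geographic outliers removed")
    return raw.with_records(df, note)


def downsample_grid(occ: OccurrenceSet, cell_km: float = 50.0,
                    origin_xy_km: tuple[float, float] = (0.0, 0.0)) -> OccurrenceSet:
    """Thin records to at most one per ``cell_km`` equal-area grid cell.

    The retained record in each cell is the earliest by year (records with
    missing years sort last), ties broken by id, which preserves the invasion
    chronology for later time-slicing. ``origin_xy_km`` anchors the grid and is
    exposed because the thinning is (mildly) sensitive to it.
    """
    df = occ.records.copy()
    x, y = equal_area_xy_km(df["longitude"].to_numpy(float),
                            df["latitude"].to_numpy(float))
    df["_cx"] = np.floor((x - origin_xy_km[0]) / cell_km).astype(int)
    df["_cy"] = np.floor((y - origin_xy_km[1]) / cell_km).astype(int)
    df["_yr"] = df["year"].fillna(np.inf)
    df = df.sort_values(["_yr", "id"], kind="stable").groupby(
        ["_cx", "_cy"], as_index=False).head(1)
    df = df.drop(columns=["_cx", "_cy", "_yr"])
    return occ.with_records(df, f"downsample: {cell_km} km equal-area grid")


# ---------------------------------------------------------------------------
# background sampling

def buffer_union_polygon(occ: OccurrenceSet, buffer_km: float = 100.0,
                         n_arc: int = 64):
    """Dissolved union of small-circle buffers around each presence point.

    Buffers are traced with ``n_arc`` azimuth steps on the sphere and unioned
    with shapely; used for GeoJSON export and visual checks (membership tests
    elsewhere use exact haversine distances).
    """
    az = np.linspace(0, 2 * math.pi, n_arc, endpoint=False)
    ang = buffer_km / EARTH_RADIUS_KM
    polys = []
    for lo, la in zip(occ.lon, occ.lat):
        la1 = math.radians(la)
        lo1 = math.radians(lo)
        lat2 = np.arcsin(np.sin(la1) * np.cos(ang)
                         + np.cos(la1) * np.sin(ang) * np.cos(az))
        lon2 = lo1 + np.arctan2(np.sin(az) * np.sin(ang) * np.cos(la1),
                                np.cos(ang) - np.sin(la1) * np.sin(lat2))
        ring = np.column_stack([np.degrees(lon2), np.degrees(lat2)])
        polys.append(Polygon(ring))
    return unary_union(polys)


def build_background(occ: OccurrenceSet, rasters: RasterStack,
                     buffer_km: float = 100.0, n: int = 10_000,
                     seed: int | None = None) -> BackgroundSample:
    """Sample latitude-weighted background points within presence buffers.

    Candidate cells are the non-masked raster cells whose centres lie within
    ``buffer_km`` (haversine) of any presence point — the dissolved buffer
    union. Cells are drawn with probability proportional to their area, i.e.
    cos(latitude) on a geographic grid, and each point is jittered uniformly
    within its cell.
    """
    if len(occ) == 0:
        raise ValueError("cannot build background from an empty occurrence set")
    rng = np.random.default_rng(seed)
    rows, cols = rasters.valid_rowcol()
    lon_c, lat_c = rasters.rowcol_to_lonlat(rows, cols)
    # distance from each valid cell centre to its nearest presence
    in_buf = np.zeros(len(rows), dtype=bool)
    chunk = 2048
    for start in range(0, len(rows), chunk):
        sl = slice(start, start + chunk)
        d = haversine_km(lon_c[sl, None], lat_c[sl, None],
                         occ.lon[None, :], occ.lat[None, :])
        in_buf[sl] = (d <= buffer_km).any(axis=1)
    if not in_buf.any():
        raise ValueError("buffer union intersects no valid raster cells")
    lon_c, lat_c = lon_c[in_buf], lat_c[in_buf]
    w = np.cos(np.radians(lat_c))
    w = np.clip(w, 0.0, None)
    if w.sum() <= 0:
        raise ValueError("all candidate cells have zero area weight")
    if n == 0:
        pts = pd.DataFrame({"longitude": [], "latitude": []})
        return BackgroundSample(pts, buffer_km)
    idx = rng.choice(len(lon_c), size=n, replace=True, p=w / w.sum())
    jx = rng.uniform(-0.5, 0.5, n) * rasters.cell_width_deg
    jy = rng.uniform(-0.5, 0.5, n) * rasters.cell_height_deg
    pts = pd.DataFrame({"longitude": lon_c[idx] + jx, "latitude": lat_c[idx] + jy})
    return BackgroundSample(pts, buffer_km)


# ---------------------------------------------------------------------------
# occupancy and time slicing

def area_of_occupancy(occ: OccurrenceSet, cell_arcsec: float = 30.0) -> int:
    """Number of distinct grid cells (default 30 arc-second) holding records.

    Cells are half-open ``[lower, upper)`` intervals of a global lon/lat grid
    anchored at (-180, -90).
    """
    if len(occ) == 0:
        return 0
    d = cell_arcsec / 3600.0
    ix = np.floor((occ.lon + 180.0) / d).astype(np.int64)
    iy = np.floor((occ.lat + 90.0) / d).astype(np.int64)
    return len(set(zip(ix.tolist(), iy.tolist())))


def time_slice(occ: OccurrenceSet, cutoff_year: int) -> OccurrenceSet:
    """Records collected up to and including ``cutoff_year``.

    Records without a year are excluded — their collection date is unknown, so
    they cannot be placed in the invasion chronology.
    """
    df = occ.records
    yr = df["year"].to_numpy(float)
    keep = ~np.isnan(yr) & (yr <= cutoff_year)
    return occ.with_records(df[keep], f"time_slice: year <= {cutoff_year}")
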