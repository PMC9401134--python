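"""Fire activity from satellite hotspot detections.

Turns raw VIIRS-style hotspot points into per-fire-day activity flags and
fire-area predictors. A "fire day" runs from local midday to the next local
midday so that a day's afternoon ignitions and the following night's smoke
belong to the same analysis day; night detections from the early-morning
overpass (before 7 am) are credited to the previous day's fire.

The burned-footprint area for a day is estimated by intersecting each
hotspot's nominal pixel footprint (375 m square) with a 500 m analysis grid
and counting unique cells at 25 ha each, which collapses double captures of
the same location by overlapping satellite swaths. Areas are additionally
split into west / south / north sectors (bearing from the reference station
±45°) which enter the regression models as separate predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "GridSpec",
    "Cluster",
    "FireDayAreas",
    "LocalProjection",
    "haversine_km",
    "bearing_deg",
    "assign_fire_day",
    "within_buffer",
    "cluster_hotspots",
    "is_active_day",
    "rasterize_footprints",
    "daily_fire_area",
    "sector_of",
    "sector_areas",
    "fire_day_table",
    "read_hotspot_csv",
]


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in kilometres between WGS84 points (degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def bearing_deg(lon_ref, lat_ref, lon, lat):
    """Initial great-circle bearing (degrees clockwise from north) from the
    reference point to each target point."""
    lam1, phi1, lam2, phi2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon_ref, lat_ref, lon, lat))
    dlon = lam2 - lam1
    y = np.sin(dlon) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


class LocalProjection:
    """Spherical transverse-Mercator projection centred on a reference point.

    Adequate for a ~150 km study buffer: distortion over that extent is far
    below the 500 m analysis-grid resolution.
    """

    def __init__(self, reference_lon: float, reference_lat: float):
        self.reference_lon = float(reference_lon)
        self.reference_lat = float(reference_lat)

    def to_xy(self, lon, lat):
        """Project lon/lat degrees to local (x, y) metres."""
        lon = np.radians(np.asarray(lon, dtype=float))
        lat = np.radians(np.asarray(lat, dtype=float))
        lon0 = math.radians(self.reference_lon)
        lat0 = math.radians(self.reference_lat)
        R = EARTH_RADIUS_KM * 1000.0
        b = np.clip(np.cos(lat) * np.sin(lon - lon0), -1.0 + 1e-15, 1.0 - 1e-15)
        x = R * np.arctanh(b)
        y = R * (np.arctan2(np.tan(lat), np.cos(lon - lon0)) - lat0)
        return x, y


@dataclass(frozen=True)
class GridSpec:
    """Regular analysis grid in projected coordinates.

    ``cell_size_m`` defaults to 500 m, i.e. 25 ha cells. The origin is the
    projected lower-left corner of the grid.
    """

    cell_size_m: float = 500.0
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self):
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size_m**2 / 1e4

    @classmethod
    def for_buffer(cls, radius_km: float = 150.0, cell_size_m: float = 500.0) -> "GridSpec":
        """Grid covering a buffer of ``radius_km`` around the projection
        origin, with the grid origin snapped to a cell multiple."""
        r = radius_km * 1000.0
        o = -math.ceil(r / cell_size_m) * cell_size_m
        return cls(cell_size_m=cell_size_m, origin_x=o, origin_y=o)


@dataclass(frozen=True)
class Cluster:
    """A single-linkage group of hotspot detections for one fire day."""

    member_ids: frozenset
    size: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "size", len(self.member_ids))


@dataclass(frozen=True)
class FireDayAreas:
    """Per-fire-day activity flag and hotspot-derived areas (hectares)."""

    fire_day: date
    active: bool
    area_total: float
    area_west: float
    area_south: float
    area_north: float
    n_hotspots: int = 0
    n_clusters: int = 0
    max_cluster_size: int = 0


def assign_fire_day(timestamp_local) -> date:
    """Map a local timestamp to its fire day (the midday-to-midday window
    start date).

    [12:00, 24:00) of date D -> D; [00:00, 07:00) of D -> D - 1 (night
    overpass credited to the previous day's fire); [07:00, 12:00) of D -> D
    (no overpass normally falls there).
    """
    ts = pd.Timestamp(timestamp_local)
    if ts.hour < 7:
        return (ts - pd.Timedelta(days=1)).date()
    return ts.date()


def within_buffer(lon, lat, reference: tuple[float, float], radius_km: float = 150.0):
    """True where the great-circle distance to ``reference`` (lon, lat) is at
    most ``radius_km``."""
    return haversine_km(reference[0], reference[1], lon, lat) <= radius_km


def cluster_hotspots(points: pd.DataFrame, link_km: float = 5.0) -> list[Cluster]:
    """Single-linkage spatial clusters of one fire day's hotspots.

    Two hotspots are linked when their great-circle distance is at most
    ``link_km``; clusters are the connected components of the resulting
    graph, so chains of nearby points merge ("within 5 km of each other"
    read as chain connectivity). The result is invariant to row order.

    Parameters
    ----------
    points : DataFrame with columns ``id``, ``lon``, ``lat``.
    """
    n = len(points)
    if n == 0:
        return []
    lon = points["lon"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float)
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    adj = csr_matrix(d <= link_km)
    _, labels = connected_components(adj, directed=False)
    ids = points["id"].to_numpy()
    clusters = [
        Cluster(frozenset(ids[labels == k])) for k in range(labels.max() + 1)
    ]
    clusters.sort(key=lambda c: min(str(i) for i in c.member_ids))
    return clusters


def is_active_day(clusters: list[Cluster]) -> bool:
    """An active fire day has at least one cluster of three or more hotspots;
    days with only one or two isolated detections are excluded."""
    return any(c.size >= 3 for c in clusters)


def rasterize_footprints(
    xy: np.ndarray,
    grid: GridSpec,
    footprint_m: float = 375.0,
    mode: str = "footprint",
) -> set[tuple[int, int]]:
    """Unique grid cells intersected by hotspot footprints.

    Each hotspot is represented as an axis-aligned square of side
    ``footprint_m`` (the nominal VIIRS pixel) centred on its projected
    location; a cell counts when the overlap has positive area, so a
    footprint edge lying exactly on a grid line does not capture the
    neighbouring cell. ``mode="point"`` instead assigns only the cell
    containing the point.

    Parameters
    ----------
    xy : (n, 2) array of projected coordinates in metres.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    c = grid.cell_size_m
    if len(xy) == 0:
        return set()
    if mode == "point":
        ij = np.stack(
            [
                np.floor((xy[:, 0] - grid.origin_x) / c).astype(int),
                np.floor((xy[:, 1] - grid.origin_y) / c).astype(int),
            ],
            axis=1,
        )
        return set(map(tuple, np.unique(ij, axis=0)))
    if mode != "footprint":
        raise ValueError(f"unknown rasterization mode: {mode!r}")
    h = footprint_m / 2.0
    x, y = xy[:, 0] - grid.origin_x, xy[:, 1] - grid.origin_y
    i_lo = np.floor((x - h) / c).astype(int)
    i_hi = np.ceil((x + h) / c).astype(int) - 1
    j_lo = np.floor((y - h) / c).astype(int)
    j_hi = np.ceil((y + h) / c).astype(int) - 1
    pieces = []
    for di in range(int((i_hi - i_lo).max()) + 1):
        for dj in range(int((j_hi - j_lo).max()) + 1):
            m = (i_lo + di <= i_hi) & (j_lo + dj <= j_hi)
            if m.any():
                pieces.append(np.stack([i_lo[m] + di, j_lo[m] + dj], axis=1))
    return set(map(tuple, np.unique(np.concatenate(pieces), axis=0)))


def daily_fire_area(
    xy: np.ndarray, grid: GridSpec, footprint_m: float = 375.0, mode: str = "footprint"
) -> float:
    """Fire area in hectares: unique intersected cells x cell area (25 ha
    for the default 500 m grid)."""
    return len(rasterize_footprints(xy, grid, footprint_m, mode)) * grid.cell_area_ha


def sector_of(bearing: float) -> str:
    """Sector of a bearing from the reference station.

    west = 270°±45° -> [225, 315); north = 360°±45° -> [315, 360) u [0, 45);
    south = 180°±45° -> [135, 225). The eastern quadrant [45, 135) belongs
    to no modelled sector ("none"): it still counts toward the total area
    but to no sector predictor.
    """
    b = float(bearing) % 360.0
    if 225.0 <= b < 315.0:
        return "west"
    if b >= 315.0 or b < 45.0:
        return "north"
    if 135.0 <= b < 225.0:
        return "south"
    return "none"


def sector_areas(
    points: pd.DataFrame,
    reference: tuple[float, float],
    grid: GridSpec,
    fire_day: date | None = None,
    link_km: float = 5.0,
    footprint_m: float = 375.0,
    mode: str = "footprint",
    projection: LocalProjection | None = None,
) -> FireDayAreas:
    """Total and per-sector fire areas for one fire day's in-buffer hotspots.

    Hotspots are partitioned by the bearing of their centre point from the
    reference; each partition is rasterized separately, so a footprint is
    never split across sectors. The total uses the unpartitioned set.
    """
    proj = projection or LocalProjection(*reference)
    if len(points):
        x, y = proj.to_xy(points["lon"].to_numpy(), points["lat"].to_numpy())
        xy = np.column_stack([x, y])
        brg = bearing_deg(reference[0], reference[1], points["lon"].to_numpy(), points["lat"].to_numpy())
        sectors = np.array([sector_of(b) for b in brg])
    else:
        xy = np.empty((0, 2))
        sectors = np.array([], dtype=str)
    clusters = cluster_hotspots(points, link_km=link_km) if len(points) else []
    areas = {}
    for name in ("west", "south", "north"):
        areas[name] = daily_fire_area(xy[sectors == name], grid, footprint_m, mode)
    total = daily_fire_area(xy, grid, footprint_m, mode)
    return FireDayAreas(
        fire_day=fire_day,
        active=is_active_day(clusters),
        area_total=total,
        area_west=areas["west"],
        area_south=areas["south"],
        area_north=areas["north"],
        n_hotspots=len(points),
        n_clusters=len(clusters),
        max_cluster_size=max((c.size for c in clusters), default=0),
    )


def fire_day_table(
    hotspots: pd.DataFrame,
    reference: tuple[float, float],
    buffer_km: float = 150.0,
    grid: GridSpec | None = None,
    link_km: float = 5.0,
    footprint_m: float = 375.0,
    mode: str = "footprint",
) -> pd.DataFrame:
    """Per-fire-day activity and areas for a raw hotspot table.

    Filters to the study buffer, assigns each detection to its
    midday-to-midday fire day, and computes clustering and sector areas per
    day. Returns one row per fire day present in the filtered data, sorted
    by date.

    Parameters
    ----------
    hotspots : DataFrame with ``id``, ``lon``, ``lat``, ``timestamp_local``.
    """
    grid = grid or GridSpec.for_buffer(buffer_km)
    proj = LocalProjection(*reference)
    if len(hotspots) == 0:
        return pd.DataFrame(
            columns=[
                "fire_day", "active", "area_total_ha", "area_west_ha",
                "area_south_ha", "area_north_ha", "n_hotspots", "n_clusters",
                "max_cluster_size",
            ]
        )
    pts = hotspots.loc[
        within_buffer(hotspots["lon"].to_numpy(), hotspots["lat"].to_numpy(), reference, buffer_km)
    ].copy()
    pts.attrs = {}  # metadata would otherwise be deep-copied on every slice
    ts = pd.to_datetime(pts["timestamp_local"])
    pts["fire_day"] = (ts.dt.normalize() - pd.to_timedelta((ts.dt.hour < 7).astype(int), unit="D")).dt.date
    rows = []
    for day, group in pts.groupby("fire_day", sort=True):
        fa = sector_areas(
            group, reference, grid, fire_day=day, link_km=link_km,
            footprint_m=footprint_m, mode=mode, projection=proj,
        )
        rows.append(
            {
                "fire_day": day,
                "active": fa.active,
                "area_total_ha": fa.area_total,
                "area_west_ha": fa.area_west,
                "area_south_ha": fa.area_south,
                "area_north_ha": fa.area_north,
                "n_hotspots": fa.n_hotspots,
                "n_clusters": fa.n_clusters,
                "max_cluster_size": fa.max_cluster_size,
            }
        )
    return pd.DataFrame(rows)


def read_hotspot_csv(path, tz_offset_hours: float = 0.0) -> pd.DataFrame:
    """Read a FIRMS-style hotspot CSV (latitude, longitude, acq_date,
    acq_time, daynight) into the internal hotspot table.

    ``acq_time`` is HHMM; ``tz_offset_hours`` shifts the acquisition time to
    local time when the file carries UTC.
    """
    raw = pd.read_csv(path)
    hhmm = raw["acq_time"].astype(int)
    ts = pd.to_datetime(raw["acq_date"]) + pd.to_timedelta(
        hhmm // 100, unit="h"
    ) + pd.to_timedelta(hhmm % 100, unit="m") + pd.Timedelta(hours=tz_offset_hours)
    return pd.DataFrame(
        {
            "id": np.arange(len(raw)),
            "lon": raw["longitude"].astype(float),
            "lat": raw["latitude"].astype(float),
            "timestamp_local": ts,
            "daynight": raw.get("daynight", pd.Series(["D"] * len(raw))),
        }
    )
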