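"""Daily model-table assembly.

Aggregates hourly station PM2.5 and hourly site weather into one model row
per active fire day: the two responses (mean and maximum of the station
daily means across the Sydney-area monitors), the 24 h lag of the regional
mean, and the weather and fire-area predictors. All daily aggregates use
the same midday-to-midday window as the fire-day definition; the coastal
wind components instead use the afternoon (2-6 pm) of the window's starting
date, to capture sea-breeze occurrence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AggregationPolicy",
    "daily_window",
    "station_daily_mean",
    "regional_responses",
    "ventilation_index",
    "afternoon_mean",
    "wind_to_speed_dir",
    "speed_dir_to_uv",
    "assemble_table",
    "PREDICTOR_COLUMNS",
]

#: Predictor columns of an assembled model row, in canonical order.
PREDICTOR_COLUMNS = [
    "lag_pm",
    "ventilation_index",
    "temperature",
    "cloud",
    "mslp_west",
    "mslp_tasman",
    "u_coast_aft",
    "v_coast_aft",
    "u_inland",
    "v_inland",
    "fire_west",
    "fire_south",
    "fire_north",
]


@dataclass(frozen=True)
class AggregationPolicy:
    """Missing-data and windowing policy for daily aggregation.

    completeness_min : minimum fraction of a window's hours that must be
        present for a station/site daily mean to count.
    min_stations : minimum number of non-missing station means required to
        form the regional responses.
    afternoon_hours : local hours defining the 2-6 pm sea-breeze window.
    vi_method : "hourly" computes speed x boundary-layer height per hour and
        averages the product over the window (the physically standard
        ventilation index); "daily_product" multiplies the daily mean speed
        by the daily mean boundary-layer height.
    """

    completeness_min: float = 0.75
    min_stations: int = 3
    afternoon_hours: frozenset = frozenset({14, 15, 16, 17})
    vi_method: str = "hourly"

    def __post_init__(self):
        if not (0.0 < self.completeness_min <= 1.0):
            raise ValueError("completeness_min must be in (0, 1]")
        if self.min_stations < 1:
            raise ValueError("min_stations must be >= 1")
        if self.vi_method not in ("hourly", "daily_product"):
            raise ValueError("vi_method must be 'hourly' or 'daily_product'")


def daily_window(fire_day) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Half-open [D 12:00, D+1 12:00) local window of a fire day."""
    start = pd.Timestamp(fire_day) + pd.Timedelta(hours=12)
    return start, start + pd.Timedelta(days=1)


def _window_label(timestamps: pd.Series) -> pd.Series:
    """Fire day owning each hourly timestamp (window membership)."""
    return (pd.to_datetime(timestamps) - pd.Timedelta(hours=12)).dt.date


def station_daily_mean(hourly: pd.DataFrame, fire_day, policy: AggregationPolicy | None = None):
    """Mean of one station's hourly values inside the fire-day window, or
    NaN when fewer than ``completeness_min`` of the 24 hours are present.

    ``hourly`` needs columns ``timestamp`` and ``value``.
    """
    policy = policy or AggregationPolicy()
    start, end = daily_window(fire_day)
    ts = pd.to_datetime(hourly["timestamp"])
    vals = hourly.loc[(ts >= start) & (ts < end), "value"].dropna()
    if len(vals) / 24.0 < policy.completeness_min:
        return np.nan
    return float(vals.mean())


def regional_responses(station_means, policy: AggregationPolicy | None = None):
    """(mean_pm, max_pm) across the non-missing station daily means.

    Returns (nan, nan) when fewer than ``min_stations`` stations report,
    flagging the day as unusable.
    """
    policy = policy or AggregationPolicy()
    vals = np.asarray(pd.Series(station_means).dropna(), dtype=float)
    if len(vals) < policy.min_stations:
        return np.nan, np.nan
    return float(vals.mean()), float(vals.max())


def ventilation_index(u, v, pblh):
    """Ventilation index: wind speed times planetary boundary-layer height
    (m^2 s^-1). Low values indicate poor pollutant dispersal."""
    pblh = np.asarray(pblh, dtype=float)
    if np.any(pblh <= 0):
        raise ValueError("boundary-layer height must be positive")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return np.hypot(u, v) * pblh


def afternoon_mean(hourly: pd.DataFrame, fire_day, policy: AggregationPolicy | None = None):
    """Mean over the afternoon hours (default 14-17 local, i.e. 2-6 pm) of
    the fire day's starting calendar date; NaN when all are missing."""
    policy = policy or AggregationPolicy()
    d = pd.Timestamp(fire_day).date()
    ts = pd.to_datetime(hourly["timestamp"])
    sel = (ts.dt.date == d) & ts.dt.hour.isin(policy.afternoon_hours)
    vals = hourly.loc[sel, "value"].dropna()
    if len(vals) == 0:
        return np.nan
    return float(vals.mean())


def wind_to_speed_dir(u, v):
    """Convert (u, v) wind components to (speed, meteorological direction).

    Direction is the compass bearing the wind blows *from* (180 = southerly,
    90 = easterly, i.e. negative U). Direction is NaN at zero speed.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = np.hypot(u, v)
    direction = (270.0 - np.degrees(np.arctan2(v, u))) % 360.0
    direction = np.where(speed == 0.0, np.nan, direction)
    if speed.ndim == 0:
        return float(speed), float(direction)
    return speed, direction


def speed_dir_to_uv(speed, direction):
    """Inverse of :func:`wind_to_speed_dir`: (speed, direction the wind is
    from, degrees) back to (u, v) components."""
    speed = np.asarray(speed, dtype=float)
    theta = np.radians(np.asarray(direction, dtype=float))
    u = -speed * np.sin(theta)
    v = -speed * np.cos(theta)
    if speed.ndim == 0:
        return float(u), float(v)
    return u, v


def _pivot_site(weather: pd.DataFrame, site: str) -> pd.DataFrame:
    w = weather.loc[weather["site"] == site]
    wide = w.pivot_table(index="timestamp", columns="variable", values="value", aggfunc="mean")
    wide.index = pd.to_datetime(wide.index)
    return wide.sort_index()


def _daily_means(wide: pd.DataFrame, policy: AggregationPolicy) -> pd.DataFrame:
    """Midday-to-midday means of every column, masked by completeness."""
    lbl = _window_label(pd.Series(wide.index))
    grouped = wide.groupby(lbl.values)
    means = grouped.mean()
    counts = grouped.count()
    return means.where(counts / 24.0 >= policy.completeness_min)


def assemble_table(
    pm_hourly: pd.DataFrame,
    weather_hourly: pd.DataFrame,
    fire_day_areas: pd.DataFrame,
    policy: AggregationPolicy | None = None,
    months: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9),
) -> pd.DataFrame:
    """One model row per active fire day in the hazard-reduction-burn season.

    Parameters
    ----------
    pm_hourly : long table ``station, timestamp, value`` of hourly PM2.5.
    weather_hourly : long table ``site, timestamp, variable, value``; sites
        ``western`` (u, v, temperature, pblh, cloud, mslp), ``coastal``
        (u, v), ``inland`` (u, v) and ``tasman`` (mslp).
    fire_day_areas : output of :func:`smokecast.fire.fire_day_table`.
    months : calendar months retained (default March-September).

    Rows with any missing field, with no computable 24 h lag, outside the
    retained months, or on inactive fire days are dropped (with a log
    message); the result is sorted by date.
    """
    policy = policy or AggregationPolicy()

    # Station daily means over midday-to-midday windows, then the regional
    # mean/max responses. The lag uses the full continuous record, not only
    # active days, so gaps of inactive days still yield a prior-24 h mean.
    pm = pm_hourly.copy()
    pm["timestamp"] = pd.to_datetime(pm["timestamp"])
    pm["fire_day"] = _window_label(pm["timestamp"])
    g = pm.groupby(["fire_day", "station"])["value"]
    st_means = g.mean().where(g.count() / 24.0 >= policy.completeness_min).unstack("station")
    n_ok = st_means.notna().sum(axis=1)
    mean_pm = st_means.mean(axis=1).where(n_ok >= policy.min_stations)
    max_pm = st_means.max(axis=1).where(n_ok >= policy.min_stations)
    lag_pm = mean_pm.reindex([d - timedelta(days=1) for d in mean_pm.index])
    lag_pm.index = mean_pm.index

    western = _pivot_site(weather_hourly, "western")
    coastal = _pivot_site(weather_hourly, "coastal")
    inland = _pivot_site(weather_hourly, "inland")
    tasman = _pivot_site(weather_hourly, "tasman")

    if policy.vi_method == "hourly":
        western = western.assign(
            vi=ventilation_index(western["u"], western["v"], western["pblh"])
        )
    west_daily = _daily_means(western, policy)
    if policy.vi_method == "daily_product":
        west_daily["vi"] = ventilation_index(
            west_daily["u"], west_daily["v"], west_daily["pblh"]
        )
    inland_daily = _daily_means(inland, policy)
    tasman_daily = _daily_means(tasman, policy)

    # Afternoon coastal winds: hours 14-17 of the window's start date.
    ct = coastal.reset_index(names="timestamp")
    aft = ct[ct["timestamp"].dt.hour.isin(policy.afternoon_hours)]
    aft_daily = aft.groupby(aft["timestamp"].dt.date)[["u", "v"]].mean()

    fa = fire_day_areas.set_index("fire_day")
    active_days = fa.index[fa["active"].astype(bool)]

    rows = []
    dropped = []
    for day in sorted(active_days):
        if pd.Timestamp(day).month not in months:
            continue
        row = {
            "fire_day": day,
            "mean_pm": mean_pm.get(day, np.nan),
            "max_pm": max_pm.get(day, np.nan),
            "lag_pm": lag_pm.get(day, np.nan),
            "ventilation_index": west_daily["vi"].get(day, np.nan),
            "temperature": west_daily["temperature"].get(day, np.nan),
            "cloud": west_daily["cloud"].get(day, np.nan),
            "mslp_west": west_daily["mslp"].get(day, np.nan),
            "mslp_tasman": tasman_daily["mslp"].get(day, np.nan),
            "u_coast_aft": aft_daily["u"].get(day, np.nan),
            "v_coast_aft": aft_daily["v"].get(day, np.nan),
            "u_inland": inland_daily["u"].get(day, np.nan),
            "v_inland": inland_daily["v"].get(day, np.nan),
            "fire_west": fa.loc[day, "area_west_ha"],
            "fire_south": fa.loc[day, "area_south_ha"],
            "fire_north": fa.loc[day, "area_north_ha"],
            "month": pd.Timestamp(day).month,
        }
        if any(pd.isna(v) for k, v in row.items() if k != "fire_day"):
            dropped.append(day)
            continue
        rows.append(row)
    if dropped:
        logger.info("dropped %d active fire days with incomplete data: %s",
                    len(dropped), ", ".join(str(d) for d in dropped[:10]))
    out = pd.DataFrame(rows, columns=["fire_day", "mean_pm", "max_pm", *PREDICTOR_COLUMNS, "month"])
    return out.sort_values("fire_day").reset_index(drop=True)
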