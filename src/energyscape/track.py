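"""Daily energetics along archival-tag tracks.

Movement cost along a track combines horizontal travel (great-circle
distance between consecutive daily geolocations, smoothed with a 7-day
moving mean to damp geolocation error) with vertical travel (half the total
vertical excursion, descents assumed nearly free).  The 3-D daily distance
— a scalar sum of the two components by default — converts to body lengths
per second using the fish's interpolated daily length; the metabolic model
at that speed and the tag's mean daily ambient temperature gives the daily
cost, the observed daily Heat Increment of Feeding drives the ingestion
model, and the balance follows the fixed loss accounting.

``reexperience_track`` replays a track's positions and observed speeds
against two gridded environmental periods to ask how the same migration
would fare under a changed ocean.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .energetics import (
    EnergeticsConstants,
    ModelChain,
    daily_balance,
    length_to_weight,
    mo2_to_kj,
    predict_ingested,
)
from .hif import compute_daily_hif, daily_hif_frame, estimate_baseline, solar_offset_hours

logger = logging.getLogger("energyscape")

__all__ = [
    "great_circle_km",
    "smooth_distances",
    "vertical_km",
    "speed_bls",
    "daily_tag_summaries",
    "track_daily_energetics",
    "reexperience_track",
]

EARTH_RADIUS_KM = 6371.0


def great_circle_km(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM):
    """Haversine great-circle distance (km) between two points."""
    for la in (lat1, lat2):
        if np.any(np.abs(np.asarray(la, dtype=float)) > 90):
            raise ValueError("latitudes must be in [-90, 90]")
    p1, p2 = np.deg2rad(np.asarray(lat1, dtype=float)), np.deg2rad(np.asarray(lat2, dtype=float))
    dp = p2 - p1
    dl = np.deg2rad(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    out = 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def smooth_distances(daily_km, window: int = 7) -> np.ndarray:
    """Centered moving mean of a daily distance series; edges use whatever
    part of the window is available, so length is preserved."""
    x = pd.Series(np.asarray(daily_km, dtype=float))
    if len(x) < window:
        logger.warning("distance series shorter than %d-day window; passing through", window)
        return x.to_numpy()
    return x.rolling(window, center=True, min_periods=1).mean().to_numpy()


def vertical_km(depths_m, gap_mask=None) -> float:
    """Daily vertical travel: half the summed |depth changes|, in km.

    Descents are assumed to cost little, hence the factor one half.  Changes
    across flagged gaps (``gap_mask`` True marks missing samples) are
    excluded.
    """
    z = np.asarray(depths_m, dtype=float)
    if gap_mask is not None:
        z = z.copy()
        z[np.asarray(gap_mask, dtype=bool)] = np.nan
    dz = np.abs(np.diff(z))
    return float(0.5 * np.nansum(dz) / 1000.0)


def speed_bls(horizontal_km, vertical_km_, length_cm):
    """Total daily 3-D distance (scalar sum, km) -> body lengths per second."""
    L = np.asarray(length_cm, dtype=float)
    if np.any(L <= 0):
        raise ValueError("length must be positive")
    total_m = (np.asarray(horizontal_km, dtype=float)
               + np.asarray(vertical_km_, dtype=float)) * 1000.0
    out = total_m / 86400.0 / (L / 100.0)
    return float(out) if out.ndim == 0 else out


def daily_tag_summaries(tag) -> pd.DataFrame:
    """Per-solar-day summaries of a tag's minute trace.

    Returns a frame indexed like ``tag.daily`` with columns: mean ambient
    temperature across all depths, mean depth inside the solar day window
    (06:30-17:30 solar, the fully-day hours) and night window, and vertical
    travel (km).  Used both for depth-model training and track energetics.
    """
    offset = solar_offset_hours(tag.mean_lon)
    ts = pd.to_datetime(tag.minute["timestamp"])
    t_solar = ts + pd.Timedelta(hours=offset)
    day_lbl = t_solar.dt.floor("D")
    solar_hour = t_solar.dt.hour + t_solar.dt.minute / 60.0
    is_day = (solar_hour >= 6.5) & (solar_hour < 17.5)
    is_night = (solar_hour < 5.5) | (solar_hour >= 18.5)

    g = pd.DataFrame({
        "day": day_lbl.values,
        "depth": tag.minute["depth_m"].values,
        "ambient": tag.minute["ambient_temp_C"].values,
        "is_day": is_day.values, "is_night": is_night.values,
    })
    rows = []
    for day, sub in g.groupby("day", sort=True):
        z = sub["depth"].to_numpy()
        rows.append({
            "date": pd.Timestamp(day),
            "ambient_temp_C": float(np.nanmean(sub["ambient"])),
            "day_depth_m": float(np.nanmean(z[sub["is_day"].to_numpy()]))
            if sub["is_day"].any() else np.nan,
            "night_depth_m": float(np.nanmean(z[sub["is_night"].to_numpy()]))
            if sub["is_night"].any() else np.nan,
            "vertical_km": vertical_km(z),
            "n_minutes": len(sub),
        })
    return pd.DataFrame(rows)


def _observed_speeds(tag, c: EnergeticsConstants) -> pd.DataFrame:
    """Daily smoothed horizontal km, vertical km, speeds and weights."""
    daily = tag.daily.reset_index(drop=True)
    lat, lon = daily["lat"].to_numpy(), daily["lon"].to_numpy()
    dist = np.zeros(len(daily))
    dist[1:] = great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    smooth = smooth_distances(dist)

    summ = daily_tag_summaries(tag).set_index("date")
    vkm = summ["vertical_km"].reindex(pd.to_datetime(daily["date"])).fillna(0.0).to_numpy()
    amb = summ["ambient_temp_C"].reindex(pd.to_datetime(daily["date"])).to_numpy()

    lengths = daily["length_cm"].to_numpy(dtype=float)
    out = pd.DataFrame({
        "date": daily["date"], "lat": lat, "lon": lon,
        "horizontal_km": smooth, "vertical_km": vkm,
        "total_km": smooth + vkm,
        "length_cm": lengths,
        "weight_kg": length_to_weight(lengths, c),
        "speed_bls": speed_bls(smooth, vkm, lengths),
        "ambient_temp_C": amb,
    })
    return out


def track_daily_energetics(tag, models: ModelChain, c: EnergeticsConstants,
                           daily_hif: pd.DataFrame | None = None) -> pd.DataFrame:
    """Observed-mode daily energetics along one tag track.

    Ambient temperature is the tag's mean daily external temperature across
    all depths; movement cost is the metabolic model at the observed 3-D
    speed over 24 h with the interpolated daily weight; kJ ingested is the
    ingestion model applied to the observed daily HIF (extracted from the
    body-temperature trace unless a precomputed frame is supplied) at the
    default finfish fraction; balance applies the fixed loss accounting.
    """
    base = _observed_speeds(tag, c)
    if daily_hif is None:
        baseline = estimate_baseline(tag.minute)
        daily_hif = daily_hif_frame(compute_daily_hif(
            tag.minute, baseline, lon_offset_hours=solar_offset_hours(tag.mean_lon)))
    hif = daily_hif.set_index("date")["hif"].reindex(
        pd.to_datetime(base["date"])).to_numpy()
    hif = np.where(np.isfinite(hif), np.maximum(hif, 0.0), 0.0)

    mo2 = np.maximum(models.cost.predict(pd.DataFrame({
        "temperature_C": base["ambient_temp_C"], "speed_bls": base["speed_bls"],
    })), 0.0)
    cost = mo2_to_kj(mo2, base["weight_kg"].to_numpy(), 24.0, c)
    ingested = predict_ingested(models.ingestion, hif,
                                base["ambient_temp_C"].to_numpy(),
                                c.pct_finfish_default)
    out = base.copy()
    out["hif"] = hif
    out["movement_cost_kj"] = cost
    out["ingested_kj"] = ingested
    out["balance_kj"] = daily_balance(ingested, cost, c)
    return out


def _field_mode_balance(tag, env, models: ModelChain, c: EnergeticsConstants,
                        speeds: pd.DataFrame) -> np.ndarray:
    """Daily balance with environmental drivers taken from gridded fields
    (HIF from the foraging model, temperatures from the profile rule at the
    predicted diel depths) and the observed daily speeds."""
    from .astro import day_length_hours, moon_fraction
    from .seascape import temp_at_depth

    dates = pd.to_datetime(speeds["date"])
    lat = speeds["lat"].to_numpy()
    lon = speeds["lon"].to_numpy()
    doy = dates.dt.dayofyear.to_numpy()
    mf = (doy % 365) * 12.0 / 365.0
    sst = env.sample("sst", lat, lon, mf)
    t200 = env.sample("t200", lat, lon, mf)
    o2d = env.sample("o2depth_3p5", lat, lon, mf)
    mz = env.sample("mesozoo", lat, lon, mf)
    moon = moon_fraction(dates.to_numpy())
    day_h = day_length_hours(lat, dates.to_numpy())

    env_df = pd.DataFrame({"t200": t200, "moon_pct": moon, "o2depth_3p5": o2d})
    z_day = np.clip(models.depth_day.predict(env_df), 0.0, 200.0)
    z_night = np.clip(models.depth_night.predict(env_df), 0.0, 200.0)
    t_day = temp_at_depth(sst, t200, z_day)
    t_night = temp_at_depth(sst, t200, z_night)
    t_amb = (day_h * t_day + (24.0 - day_h) * t_night) / 24.0

    mo2 = np.maximum(models.cost.predict(pd.DataFrame({
        "temperature_C": t_amb, "speed_bls": speeds["speed_bls"],
    })), 0.0)
    cost = mo2_to_kj(mo2, speeds["weight_kg"].to_numpy(), 24.0, c)
    hif = np.maximum(models.hif.predict(pd.DataFrame({
        "mesozoo": mz, "length_cm": speeds["length_cm"],
        "day_length_h": day_h,
    })), 0.0)
    ingested = predict_ingested(models.ingestion, hif, t_day, c.pct_finfish_default)
    return daily_balance(ingested, cost, c)


def reexperience_track(tag, env_hist, env_fut, models: ModelChain,
                       c: EnergeticsConstants) -> pd.DataFrame:
    """Replay a track under historical versus future environmental fields.

    Both periods use the observed daily swimming speeds and positions; only
    the environmental drivers differ.  Returns per-day historical and future
    balances, their difference (future minus historical), and 7-day running
    means of each.
    """
    speeds = _observed_speeds(tag, c)
    b_hist = _field_mode_balance(tag, env_hist, models, c, speeds)
    b_fut = _field_mode_balance(tag, env_fut, models, c, speeds)
    out = pd.DataFrame({
        "date": speeds["date"], "lat": speeds["lat"], "lon": speeds["lon"],
        "balance_hist_kj": b_hist, "balance_fut_kj": b_fut,
        "delta_balance_kj": b_fut - b_hist,
    })
    for col in ("balance_hist_kj", "balance_fut_kj", "delta_balance_kj"):
        out[col + "_7d"] = smooth_distances(out[col].to_numpy())
    return out
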