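"""Seeded synthetic generators for every input class the pipeline consumes.

The real inputs — archival-tag records from juvenile albacore, gridded ocean
fields, and captive-tuna laboratory tables — are restricted or require large
downloads, so the package ships generators that emulate their statistical
structure:

* monthly environmental fields (SST, upper-200 m mean temperature, depth of
  the 3.5 ml/L oxygen surface, mesozooplankton biomass) on a cell-centered
  regular grid, with a poleward SST gradient, seasonal cycles, and a
  prescribed warming/productivity perturbation for the "future" period;
* per-fish tag records: a seeded daily random walk plus 1-min depth,
  body-temperature and ambient-temperature traces in which feeding events
  are trapezoidal visceral-warming pulses with exact closed-form areas;
* respirometry (temperature x swimming speed -> MO2) and feeding-trial
  (meal energy vs. HIF, temperature, diet) tables drawn from stated
  parametric surfaces.

Every generated object stores its generating parameters ("truth") so that
downstream recovery tests never re-derive ground truth from the generated
data itself.  Same seed + same config -> identical output.

Grid longitudes are stored monotonically in degrees east on [0, 360) because
the default North Pacific domain crosses the antimeridian; ``wrap_lon``
converts to [-180, 180) for display.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "SyntheticConfig",
    "EnvFieldSet",
    "TagRecord",
    "RespirometryTable",
    "FeedingTrialTable",
    "generate_env_fields",
    "generate_tag_record",
    "generate_tag_records",
    "generate_respirometry",
    "generate_feeding_trials",
    "wrap_lon",
]

ENV_VARS = ("sst", "t200", "o2depth_3p5", "mesozoo")


def wrap_lon(lon):
    """Degrees east on [0, 360) -> [-180, 180)."""
    return (np.asarray(lon) + 180.0) % 360.0 - 180.0


class ConfigurationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study conditions for all generators.

    The defaults emulate the real study's setting: a North Pacific domain
    (20-60N, 120E-110W) at 1 degree, 12 monthly climatological fields per
    30-year period, ~2 year tag deployments, a +2 C end-of-century warming
    under a moderate-emissions scenario, and a modest poleward shift in
    mesozooplankton (south-of-40N decline, north-of-40N increase).
    """

    seed: int = 0
    n_fish: int = 3
    deployment_days: int = 120
    lat_min: float = 20.0
    lat_max: float = 60.0
    lon_min: float = 120.0   # degrees east; domain crosses the antimeridian
    lon_max: float = 250.0   # 250E == 110W
    resolution: float = 1.0
    months: int = 12
    warming_offset: float = 2.0          # C added to future SST and T200
    zoo_split_lat: float = 40.0
    zoo_trend: dict = field(default_factory=lambda: {"south": 0.85, "north": 1.10})
    noise_sd: dict = field(default_factory=lambda: {
        "sst": 0.2, "t200": 0.2, "o2depth_3p5": 5.0, "mesozoo": 30.0,
        "body_temp": 0.05, "depth": 5.0, "ambient": 0.2,
        "mo2": 10.0, "kj": 100.0,
    })

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be > 0")
        if self.deployment_days < 14:
            raise ConfigurationError("deployment_days must be >= 14 (7-day smoothing)")
        if self.warming_offset < 0:
            raise ConfigurationError("warming_offset must be >= 0")
        if not (-90 <= self.lat_min < self.lat_max <= 90):
            raise ConfigurationError("invalid latitude bounds")
        if not (0 <= self.lon_min < self.lon_max <= 360):
            raise ConfigurationError("invalid longitude bounds (degrees east, [0, 360])")

    def sd(self, var: str) -> float:
        return float(self.noise_sd.get(var, 0.0))

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center latitudes (ascending) and longitudes (degrees east)."""
        r = self.resolution
        n_lat = int(round((self.lat_max - self.lat_min) / r))
        n_lon = int(round((self.lon_max - self.lon_min) / r))
        lats = self.lat_min + r * (np.arange(n_lat) + 0.5)
        lons = self.lon_min + r * (np.arange(n_lon) + 0.5)
        return lats, lons


def _source_key(source_id: str) -> int:
    return zlib.crc32(source_id.encode()) % (2 ** 20)


# ---------------------------------------------------------------------------
# environmental fields
# ---------------------------------------------------------------------------

@dataclass
class EnvFieldSet:
    """Gridded monthly fields for one source (obs-like or one ESM) and period."""

    ds: xr.Dataset
    source_id: str
    period: str

    @property
    def lats(self) -> np.ndarray:
        return self.ds["lat"].values

    @property
    def lons(self) -> np.ndarray:
        return self.ds["lon"].values

    def sample(self, var: str, lat, lon, month_frac) -> np.ndarray:
        """Nearest-cell, month-interpolated value(s).

        ``month_frac`` is a fractional month position in [0, 12) (e.g. from
        day-of-year * 12/365.25); monthly values are taken as mid-month and
        interpolated linearly with wraparound.
        """
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float)) % 360.0
        mf = np.broadcast_to(np.atleast_1d(np.asarray(month_frac, dtype=float)), lat.shape)
        ilat = np.clip(np.searchsorted(self.lats, lat), 1, len(self.lats) - 1)
        ilat = np.where(np.abs(self.lats[ilat] - lat) <= np.abs(self.lats[ilat - 1] - lat),
                        ilat, ilat - 1)
        ilon = np.clip(np.searchsorted(self.lons, lon), 1, len(self.lons) - 1)
        ilon = np.where(np.abs(self.lons[ilon] - lon) <= np.abs(self.lons[ilon - 1] - lon),
                        ilon, ilon - 1)
        vals = self.ds[var].values  # (month, lat, lon)
        nm = vals.shape[0]
        pos = mf - 0.5
        m0 = np.floor(pos).astype(int) % nm
        m1 = (m0 + 1) % nm
        w = pos - np.floor(pos)
        v0 = vals[m0, ilat, ilon]
        v1 = vals[m1, ilat, ilon]
        return (1 - w) * v0 + w * v1

    def to_netcdf(self, path) -> None:
        ds = self.ds.copy()
        ds.attrs.update(source_id=self.source_id, period=self.period,
                        grid="cell-centered regular lat/lon",
                        lon_convention="degrees_east [0, 360)")
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvFieldSet":
        ds = xr.load_dataset(path, engine="scipy")
        return cls(ds=ds, source_id=str(ds.attrs.get("source_id", "unknown")),
                   period=str(ds.attrs.get("period", "unknown")))


def generate_env_fields(cfg: SyntheticConfig, period: str = "historical",
                        source_id: str = "obs") -> EnvFieldSet:
    """Monthly SST, T200, O2-3.5 depth and mesozooplankton for one source.

    Construction (all smooth analytic surfaces plus seeded Gaussian noise):
    SST decreases poleward with an August-peaking seasonal cycle; T200 is SST
    minus a positive stratification offset (larger in summer); mesozooplankton
    increases poleward and toward the eastern boundary with an early-summer
    peak; the O2-3.5 surface shoals in a fixed offshore band.  The future
    period applies ``warming_offset`` to SST/T200 and the latitude-banded
    ``zoo_trend`` factors to mesozooplankton on the *same* noise draw, so a
    zero perturbation reproduces the historical fields exactly.

    Small deterministic per-source offsets (hashed from ``source_id``) give
    an ensemble of sources genuine spread.
    """
    if period not in ("historical", "future"):
        raise ConfigurationError(f"unknown period {period!r}")
    lats, lons = cfg.grid()
    months = np.arange(1, cfg.months + 1)
    M, LA, LO = np.meshgrid(months, lats, lons, indexing="ij")

    skey = _source_key(source_id)
    sst_off = ((skey % 997) / 997.0 - 0.5) * 1.2          # +-0.6 C between sources
    zoo_fac = 1.0 + (((skey // 997) % 991) / 991.0 - 0.5) * 0.25
    warm_fac = 1.0 + (((skey // 7) % 983) / 983.0 - 0.5) * 0.4  # source-varying warming

    seas = np.cos(2 * np.pi * (M - 8.0) / 12.0)            # peaks in August
    xe = (LO - cfg.lon_min) / max(cfg.lon_max - cfg.lon_min, 1e-9)

    sst = 29.0 - 0.45 * (LA - 20.0) + 3.5 * seas + sst_off
    strat = 3.5 + 1.5 * seas                                # positive everywhere
    t200 = sst - strat
    mesozoo = (600.0 + 15.0 * (LA - 20.0) + 300.0 * xe
               + 250.0 * np.cos(2 * np.pi * (M - 6.0) / 12.0)) * zoo_fac
    band_center = cfg.lon_min + 0.55 * (cfg.lon_max - cfg.lon_min)
    o2depth = 280.0 - 160.0 * np.exp(-(((LO - band_center) / 25.0) ** 2)) + 5.0 * seas

    fields = {"sst": sst, "t200": t200, "o2depth_3p5": o2depth, "mesozoo": mesozoo}
    for i, var in enumerate(ENV_VARS):
        sd = cfg.sd(var)
        if sd > 0:
            rng = np.random.default_rng([cfg.seed, skey, i])
            fields[var] = fields[var] + rng.normal(0.0, sd, size=fields[var].shape)

    if period == "future":
        dT = cfg.warming_offset * warm_fac if cfg.warming_offset > 0 else 0.0
        fields["sst"] = fields["sst"] + dT
        fields["t200"] = fields["t200"] + dT
        zfac = np.where(LA < cfg.zoo_split_lat,
                        float(cfg.zoo_trend.get("south", 1.0)),
                        float(cfg.zoo_trend.get("north", 1.0)))
        fields["mesozoo"] = fields["mesozoo"] * zfac

    fields["mesozoo"] = np.maximum(fields["mesozoo"], 1.0)
    fields["o2depth_3p5"] = np.maximum(fields["o2depth_3p5"], 10.0)

    ds = xr.Dataset(
        {v: (("month", "lat", "lon"), fields[v]) for v in ENV_VARS},
        coords={"month": months, "lat": lats, "lon": lons},
        attrs={
            "sst_units": "degC", "t200_units": "degC",
            "o2depth_3p5_units": "m", "mesozoo_units": "mg C m-2",
        },
    )
    if not all(np.isfinite(ds[v].values).all() for v in ENV_VARS):
        raise ConfigurationError("generated fields contain non-finite values")
    return EnvFieldSet(ds=ds, source_id=source_id, period=period)


# ---------------------------------------------------------------------------
# tag records
# ---------------------------------------------------------------------------

@dataclass
class TagRecord:
    """One archival-tagged fish: metadata, daily positions, 1-min traces.

    ``truth`` holds the generator's ground truth: per-day HIF areas (C*hour),
    the per-minute fasting baseline, per-day mean day/night depths before
    noise, and the feeding schedule actually used.
    """

    fish_id: str
    daily: pd.DataFrame          # date, lat, lon, length_cm
    minute: pd.DataFrame         # timestamp, depth_m, body_temp_C, ambient_temp_C
    release_date: pd.Timestamp
    release_length_cm: float
    recapture_length_cm: float
    truth: dict = field(default_factory=dict)

    @property
    def mean_lon(self) -> float:
        return float(self.daily["lon"].mean())

    def to_csv(self, directory) -> tuple[str, str]:
        import os
        d = os.fspath(directory)
        p_daily = os.path.join(d, f"{self.fish_id}_daily.csv")
        p_min = os.path.join(d, f"{self.fish_id}_minute.csv")
        self.daily.to_csv(p_daily, index=False)
        self.minute.to_csv(p_min, index=False)
        return p_daily, p_min

    @classmethod
    def from_csv(cls, p_daily, p_minute, fish_id: str = "fish") -> "TagRecord":
        daily = pd.read_csv(p_daily, parse_dates=["date"])
        minute = pd.read_csv(p_minute, parse_dates=["timestamp"])
        return cls(
            fish_id=fish_id, daily=daily, minute=minute,
            release_date=daily["date"].iloc[0],
            release_length_cm=float(daily["length_cm"].iloc[0]),
            recapture_length_cm=float(daily["length_cm"].iloc[-1]),
        )


def _trapezoid_pulse(hours: np.ndarray, start: float, duration: float,
                     height: float, ramp: float) -> np.ndarray:
    """Trapezoidal excess-temperature pulse; exact area = height*(duration - ramp).

    ``hours`` are local-solar hours since day start; the pulse occupies
    [start, start + duration] with linear ramps of length ``ramp`` at each
    end (ramp=0 gives a rectangle of area height*duration).
    """
    t = hours - start
    if ramp <= 0:
        # half-open support: minute-sampled trapezoid integration is exact
        return height * ((t >= 0) & (t < duration))
    up = np.clip(t / ramp, 0.0, 1.0)
    down = np.clip((duration - t) / ramp, 0.0, 1.0)
    return height * np.minimum(up, down) * ((t >= 0) & (t <= duration))


def pulse_area(height: float, duration: float, ramp: float) -> float:
    """Closed-form area (C*hour) of the trapezoidal pulse."""
    return height * (duration - ramp)


def generate_tag_record(
    cfg: SyntheticConfig,
    fish_id: str = "fish0",
    feeding_schedule: list[tuple[int, float, float]] | str | None = "auto",
    env: EnvFieldSet | None = None,
    start_date: str | pd.Timestamp = "2011-04-01",
    pulse_ramp_h: float = 0.5,
    baseline_c: float = 16.0,
    baseline_amp_c: float = 1.0,
) -> TagRecord:
    """One synthetic tagged fish.

    feeding_schedule: list of ``(day_index, excess_C, duration_h)`` events
    (at most one per local day; overlapping events are rejected so the
    per-day area under the curve stays analytically known), the string
    "auto" for a seeded random schedule, the string "env" for a noise-free
    schedule whose daily area is a stated linear function of local
    mesozooplankton biomass and day length (requires ``env``; the
    coefficients are recorded in ``truth["hif_coeffs"]`` so foraging-model
    recovery tests can read the generating relationship), or None/[] for a
    fasting fish.
    Pulses are trapezoids with ramp ``pulse_ramp_h`` (0 gives rectangles);
    each day's exact area is recorded in ``truth["daily_hif"]``.

    Daily positions follow a seeded random walk with a seasonal east-west
    drift, kept inside the configured grid.  The 1-min body-temperature
    trace is a slowly-varying fasting baseline plus the feeding pulses plus
    Gaussian noise; the depth trace alternates deep-day/shallow-night on a
    longitude-derived solar clock; fish length grows linearly from release
    to recapture.
    """
    rng = np.random.default_rng([cfg.seed, _source_key(fish_id), 17])
    n_days = cfg.deployment_days
    start = pd.Timestamp(start_date)
    dates = pd.date_range(start, periods=n_days, freq="D")

    # --- daily random-walk positions with seasonal east-west drift
    lats_g, lons_g = cfg.grid()
    lat0 = rng.uniform(cfg.lat_min + 8, cfg.lat_max - 8)
    lon0 = rng.uniform(cfg.lon_min + 15, cfg.lon_max - 15)
    doy = dates.dayofyear.values
    drift = 0.25 * np.sin(2 * np.pi * (doy - 120) / 365.25)
    dlon = drift + rng.normal(0, 0.3, n_days)
    dlat = rng.normal(0, 0.2, n_days)
    lon = np.clip(lon0 + np.cumsum(dlon), lons_g[0], lons_g[-1])
    lat = np.clip(lat0 + np.cumsum(dlat), lats_g[0], lats_g[-1])

    # --- lengths: linear growth
    release_len = float(rng.uniform(72, 85))
    growth = float(rng.uniform(0.015, 0.03))               # cm/day
    lengths = release_len + growth * np.arange(n_days)

    # --- feeding schedule
    hif_coeffs = None
    if feeding_schedule == "auto":
        feeding_schedule = []
        for d in range(n_days):
            if rng.random() < 0.75:
                height = float(rng.uniform(0.5, 2.0))
                dur = float(rng.uniform(2.0, 8.0))
                feeding_schedule.append((d, height, dur))
    elif feeding_schedule == "env":
        if env is None:
            raise ValueError("feeding_schedule='env' requires env fields")
        from .astro import day_length_hours
        hif_coeffs = {"mz": 0.005, "dl": 0.15, "dur_h": 6.0}
        mz = env.sample("mesozoo", lat, lon, (doy % 365) * 12.0 / 365.0)
        dl = np.array([day_length_hours(la, d) for la, d in zip(lat, dates)])
        area = np.maximum(hif_coeffs["mz"] * mz + hif_coeffs["dl"] * (dl - 12.0), 0.05)
        dur = hif_coeffs["dur_h"]
        eff = dur - min(pulse_ramp_h, dur / 4.0)           # area = height * eff
        feeding_schedule = [(d, float(area[d] / eff), dur) for d in range(n_days)]
    feeding_schedule = list(feeding_schedule or [])
    seen_days = set()
    for day, height, dur in feeding_schedule:
        if not (0 <= day < n_days):
            raise ValueError(f"feeding event on day {day} outside deployment")
        if dur >= 24:
            raise ValueError("feeding pulse duration must be < 24 h")
        if day in seen_days:
            raise ValueError(f"overlapping feeding pulses on day {day}")
        seen_days.add(day)

    # --- minute-level traces, on a longitude-derived local solar clock.
    # Feeding pulses are scheduled per local-solar day so that the per-day
    # areas recorded as truth match exactly what the HIF integrator (which
    # uses the same solar clock) will compute.
    from .hif import solar_offset_hours

    n_min = n_days * 1440
    ts = pd.date_range(start, periods=n_min, freq="min")
    day_idx = np.repeat(np.arange(n_days), 1440)
    minute_of_day = np.tile(np.arange(1440), n_days)
    solar_offset_h = solar_offset_hours(float(np.mean(lon)))
    t_solar_h = np.arange(n_min) / 60.0 + solar_offset_h    # continuous solar hours
    solar_hour = t_solar_h % 24.0

    # fasting baseline: slow sinusoid, linearly interpolated between days
    base_day = baseline_c + baseline_amp_c * np.sin(2 * np.pi * np.arange(n_days) / 365.25)
    baseline = np.interp(day_idx + minute_of_day / 1440.0,
                         np.arange(n_days) + 0.5, base_day)

    excess = np.zeros(n_min)
    daily_hif_truth = np.zeros(n_days)
    for day, height, dur in feeding_schedule:
        ramp = min(pulse_ramp_h, dur / 4.0)
        # midday-centered start, constrained so the pulse lies wholly within
        # solar day `day` and within the recorded (UTC) trace
        lo = 0.25 if day > 0 else max(0.25, solar_offset_h + 1.0 / 60.0)
        hi = 23.75 - dur if day < n_days - 1 else min(23.75, 24.0 + solar_offset_h) - dur
        if lo > hi:
            raise ValueError(
                f"feeding pulse of {dur} h cannot fit inside solar day {day}")
        start_h = min(max(12.0 - dur / 2.0, lo), hi)
        excess += _trapezoid_pulse(t_solar_h - 24.0 * day, start_h, dur, height, ramp)
        daily_hif_truth[day] = pulse_area(height, dur, ramp)

    body = baseline + excess
    sd_bt = cfg.sd("body_temp")
    if sd_bt > 0:
        body = body + rng.normal(0, sd_bt, n_min)

    # depth: deep day / shallow night with smooth 1-h transitions
    if env is not None:
        o2d = env.sample("o2depth_3p5", lat, lon, (doy % 365) * 12.0 / 365.0)
        day_depth_true = np.clip(0.45 * o2d, 20.0, 190.0)
    else:
        day_depth_true = np.full(n_days, 150.0)
    night_depth_true = np.full(n_days, 30.0)
    is_day_frac = (np.clip((solar_hour - 5.5) / 1.0, 0, 1)
                   * np.clip((18.5 - solar_hour) / 1.0, 0, 1))
    # index per-day depths by solar day so daily summaries (grouped on the
    # same solar clock) recover them exactly
    solar_day = np.clip(np.floor(t_solar_h / 24.0).astype(int), 0, n_days - 1)
    depth = (night_depth_true[solar_day]
             + (day_depth_true[solar_day] - night_depth_true[solar_day]) * is_day_frac)
    sd_d = cfg.sd("depth")
    if sd_d > 0:
        depth = depth + rng.normal(0, sd_d, n_min)
    depth = np.maximum(depth, 0.0)

    # ambient temperature at the fish's depth
    if env is not None:
        mf = (doy % 365) * 12.0 / 365.0
        sst_d = env.sample("sst", lat, lon, mf)[day_idx]
        t200_d = env.sample("t200", lat, lon, mf)[day_idx]
        z = np.clip(depth, 0, 200)
        ambient = sst_d + z * (t200_d - sst_d) / 100.0
    else:
        ambient = 19.0 - 3.0 * np.clip(depth, 0, 200) / 200.0
    sd_a = cfg.sd("ambient")
    if sd_a > 0:
        ambient = ambient + rng.normal(0, sd_a, n_min)

    daily = pd.DataFrame({"date": dates, "lat": lat, "lon": lon, "length_cm": lengths})
    minute = pd.DataFrame({
        "timestamp": ts, "depth_m": depth,
        "body_temp_C": body, "ambient_temp_C": ambient,
    })
    return TagRecord(
        fish_id=fish_id, daily=daily, minute=minute,
        release_date=start, release_length_cm=release_len,
        recapture_length_cm=float(lengths[-1]),
        truth={
            "daily_hif": pd.Series(daily_hif_truth, index=dates),
            "baseline_minute": baseline,
            "baseline_day": base_day,
            "day_depth": pd.Series(day_depth_true, index=dates),
            "night_depth": pd.Series(night_depth_true, index=dates),
            "feeding_schedule": feeding_schedule,
            "hif_coeffs": hif_coeffs,
            "solar_offset_h": solar_offset_h,
            "growth_cm_per_day": growth,
        },
    )


def generate_tag_records(cfg: SyntheticConfig, env: EnvFieldSet | None = None,
                         **kwargs) -> list[TagRecord]:
    """``cfg.n_fish`` tag records with staggered release dates."""
    base = pd.Timestamp(kwargs.pop("start_date", "2011-04-01"))
    return [
        generate_tag_record(cfg, fish_id=f"fish{i}", env=env,
                            start_date=base + pd.Timedelta(days=20 * i), **kwargs)
        for i in range(cfg.n_fish)
    ]


# ---------------------------------------------------------------------------
# laboratory tables
# ---------------------------------------------------------------------------

@dataclass
class RespirometryTable:
    """Captive-tuna swim-tunnel measurements: (temperature, speed) -> MO2."""

    df: pd.DataFrame             # temperature_C, speed_bls, mo2
    params: dict                 # generating parameters (truth store)

    def surface(self, temperature, speed) -> np.ndarray:
        """Noise-free generator surface mo2 = b0 + b1*s^2 + b2*exp(b3*T)."""
        p = self.params
        return (p["b0"] + p["b1"] * np.asarray(speed, dtype=float) ** 2
                + p["b2"] * np.exp(p["b3"] * np.asarray(temperature, dtype=float)))


@dataclass
class FeedingTrialTable:
    """Captive feeding trials: meal energy vs. HIF, temperature and diet."""

    df: pd.DataFrame             # hif, temperature_C, pct_finfish, kj_ingested
    params: dict

    def surface(self, hif, temperature, pct_finfish) -> np.ndarray:
        """Noise-free kj = g0*hif*(1+g1*(T-T0))*(1+g2*(pct-70)/100)."""
        p = self.params
        return (p["g0"] * np.asarray(hif, dtype=float)
                * (1.0 + p["g1"] * (np.asarray(temperature, dtype=float) - p["T0"]))
                * (1.0 + p["g2"] * (np.asarray(pct_finfish, dtype=float) - 70.0) / 100.0))


def generate_respirometry(cfg: SyntheticConfig, n_rows: int = 200,
                          temp_range: tuple[float, float] = (10.0, 25.0),
                          speed_range: tuple[float, float] = (0.5, 3.0)) -> RespirometryTable:
    """Respirometry table from mo2 = b0 + b1*speed^2 + b2*exp(b3*T) + noise.

    The default parameters put routine MO2 in the 100-400 mg O2/kg/h range
    typical of juvenile bluefin swim-tunnel work, monotone increasing in both
    temperature and speed over the sampled band.
    """
    rng = np.random.default_rng([cfg.seed, 101])
    params = {"b0": 50.0, "b1": 30.0, "b2": 30.0, "b3": 0.06,
              "noise_sd": cfg.sd("mo2")}
    T = rng.uniform(*temp_range, n_rows)
    s = rng.uniform(*speed_range, n_rows)
    table = RespirometryTable(df=pd.DataFrame(), params=params)
    mo2 = table.surface(T, s)
    if params["noise_sd"] > 0:
        mo2 = mo2 + rng.normal(0, params["noise_sd"], n_rows)
    mo2 = np.maximum(mo2, 1.0)
    table.df = pd.DataFrame({"temperature_C": T, "speed_bls": s, "mo2": mo2})
    return table


def generate_feeding_trials(cfg: SyntheticConfig, n_rows: int = 200,
                            hif_range: tuple[float, float] = (0.0, 15.0),
                            temp_range: tuple[float, float] = (12.0, 22.0)) -> FeedingTrialTable:
    """Feeding-trial table: meal energy proportional to HIF, weakly modulated
    by temperature and the finfish fraction of the diet.

    The modulation factors are deliberately mild (a few percent across the
    sampled bands) so that the additive model structure used throughout the
    framework is a faithful description of the generated process.
    """
    rng = np.random.default_rng([cfg.seed, 202])
    params = {"g0": 400.0, "g1": 0.008, "T0": 17.0, "g2": 0.06,
              "noise_sd": cfg.sd("kj")}
    hif = rng.uniform(*hif_range, n_rows)
    T = rng.uniform(*temp_range, n_rows)
    pct = rng.choice([0.0, 30.0, 70.0, 100.0], n_rows)
    table = FeedingTrialTable(df=pd.DataFrame(), params=params)
    kj = table.surface(hif, T, pct)
    if params["noise_sd"] > 0:
        kj = kj + rng.normal(0, params["noise_sd"], n_rows)
    kj = np.maximum(kj, 0.0)
    table.df = pd.DataFrame({"hif": hif, "temperature_C": T,
                             "pct_finfish": pct, "kj_ingested": kj})
    return table
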