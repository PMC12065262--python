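"""Gridded energetic seascapes, thermal-envelope habitat change, ensembles.

Applies the fitted model chain per grid cell: diel depths from the day/night
depth models, ambient temperatures at those depths from a linear 0-200 m
profile consistent with SST and the upper-200 m mean temperature, movement
cost from the metabolic model at the fixed diel speeds weighted by day/night
hours, foraging gain from the HIF and ingestion models, and the daily kJ
balance from the loss accounting.  Cells with SST outside the favorable
thermal envelope (11-22 C inclusive by default) are masked.

Habitat change between a historical and a future period is summarized per
season (DJF/MAM/JJA/SON) as favorable-habitat area (km2), percent area
change, and the area-weighted mean kJ balance inside each period's own mask
and inside the intersection ("consistently favorable") mask; a
cross-climate-source ensemble summary reports t-based 95% confidence
intervals and flags seasons where sources disagree on the direction of
change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .astro import day_length_hours, moon_fraction
from .energetics import (
    EnergeticsConstants,
    FishState,
    daily_balance,
    mo2_to_kj,
    predict_ingested,
)
from .synthetic import EnvFieldSet

__all__ = [
    "EnergeticsMap",
    "HabitatChangeSummary",
    "day_length_hours",
    "moon_fraction",
    "temp_at_depth",
    "project_energetics",
    "cell_areas",
    "habitat_change",
    "ensemble_summary",
    "SEASONS",
]

EARTH_RADIUS_KM = 6371.0
SEASONS = {"DJF": (12, 1, 2), "MAM": (3, 4, 5), "JJA": (6, 7, 8), "SON": (9, 10, 11)}


def temp_at_depth(sst, t200, z):
    """Temperature at depth z (m) from a linear 0-200 m profile.

    T(0) = SST and the 0-200 m depth average equals t200, hence
    T(z) = SST + z * (t200 - SST) / 100.  z is clamped to [0, 200].
    """
    z = np.clip(np.asarray(z, dtype=float), 0.0, 200.0)
    out = np.asarray(sst, dtype=float) + z * (np.asarray(t200, dtype=float)
                                              - np.asarray(sst, dtype=float)) / 100.0
    return float(out) if out.ndim == 0 else out


def cell_areas(lats: np.ndarray, lons: np.ndarray,
               radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Surface area (km2) of each cell of a regular cell-centered grid:
    R^2 * cos(lat_center) * dlon * dlat (radians)."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    dlat = np.deg2rad(abs(lats[1] - lats[0])) if len(lats) > 1 else np.deg2rad(1.0)
    dlon = np.deg2rad(abs(lons[1] - lons[0])) if len(lons) > 1 else np.deg2rad(1.0)
    col = radius_km ** 2 * np.cos(np.deg2rad(lats)) * dlat * dlon
    return np.repeat(col[:, None], len(lons), axis=1)


@dataclass
class EnergeticsMap:
    """Per-cell daily energetics for one season (or month), source and period."""

    ds: xr.Dataset               # day_depth, night_depth, t_day, t_night,
    #                              cost, ingested, balance, sst  (lat, lon)
    mask: np.ndarray             # True where SST inside the thermal envelope
    season: str
    source_id: str
    period: str

    def to_netcdf(self, path) -> None:
        ds = self.ds.copy()
        ds["mask"] = (("lat", "lon"), self.mask.astype(np.int8))
        ds.attrs.update(season=self.season, source_id=self.source_id, period=self.period)
        ds.to_netcdf(path, engine="scipy")


@dataclass
class HabitatChangeSummary:
    """Thermal-habitat and balance change for one season and source."""

    season: str
    source_id: str
    area_hist_km2: float
    area_fut_km2: float
    pct_area_change: float
    balance_hist: float | None          # area-weighted mean kJ inside hist mask
    balance_fut: float | None           # inside fut mask
    balance_change: float | None        # fut - hist, per-period masks
    balance_change_consistent: float | None  # inside the intersection mask
    empty_mask: bool = False

    @property
    def area_change_km2(self) -> float:
        return self.area_fut_km2 - self.area_hist_km2


def _chain_predict(models, c: EnergeticsConstants, fish: FishState,
                   sst, t200, o2d, mz, moon_pct, day_h, coefs: dict | None = None):
    """Evaluate the full model chain on flat arrays of cell covariates.

    ``coefs`` optionally substitutes simulated coefficient vectors per slot
    ("depth", "cost", "hif", "ingestion") for posterior-ensemble runs.
    Returns a dict of flat arrays.
    """
    coefs = coefs or {}
    n = len(sst)
    env_df = pd.DataFrame({"t200": t200, "moon_pct": moon_pct, "o2depth_3p5": o2d})
    cd = coefs.get("depth")
    z_day = np.clip(models.depth_day.predict(env_df, coef=None if cd is None else cd[0]),
                    0.0, 200.0)
    z_night = np.clip(models.depth_night.predict(env_df, coef=None if cd is None else cd[1]),
                      0.0, 200.0)
    t_day = temp_at_depth(sst, t200, z_day)
    t_night = temp_at_depth(sst, t200, z_night)

    cc = coefs.get("cost")
    mo2_day = models.cost.predict(
        pd.DataFrame({"temperature_C": t_day, "speed_bls": np.full(n, c.speed_day)}),
        coef=cc)
    mo2_night = models.cost.predict(
        pd.DataFrame({"temperature_C": t_night, "speed_bls": np.full(n, c.speed_night)}),
        coef=cc)
    night_h = 24.0 - day_h
    cost = (mo2_to_kj(np.maximum(mo2_day, 0.0), fish.weight, day_h, c)
            + mo2_to_kj(np.maximum(mo2_night, 0.0), fish.weight, night_h, c))

    ch = coefs.get("hif")
    hif = np.maximum(models.hif.predict(
        pd.DataFrame({"mesozoo": mz, "length_cm": np.full(n, fish.length),
                      "day_length_h": day_h}), coef=ch), 0.0)
    ci = coefs.get("ingestion")
    ingested = predict_ingested(models.ingestion, hif, t_day,
                                c.pct_finfish_default) if ci is None else np.maximum(
        models.ingestion.predict(
            pd.DataFrame({"hif": hif, "temperature_C": t_day,
                          "pct_finfish": np.full(n, c.pct_finfish_default)}), coef=ci), 0.0)
    balance = daily_balance(ingested, cost, c)
    return {"day_depth": z_day, "night_depth": z_night, "t_day": t_day,
            "t_night": t_night, "cost": cost, "hif": hif,
            "ingested": ingested, "balance": balance}


def project_energetics(env: EnvFieldSet, models, c: EnergeticsConstants,
                       ref_fish: FishState | None = None,
                       season: str = "JJA", year: int = 2000,
                       coefs: dict | None = None) -> EnergeticsMap:
    """Seasonal energetics map for one EnvFieldSet.

    Monthly chain evaluations (mid-month date for day length and moon phase,
    cell-latitude day length weighting the diel cost split) averaged over the
    season's months; the thermal mask applies the SST envelope to the
    seasonal-mean SST with inclusive bounds.
    """
    for v in ("sst", "t200", "o2depth_3p5", "mesozoo"):
        if v not in env.ds:
            raise ValueError(f"environmental field set missing variable {v!r}")
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; expected one of {sorted(SEASONS)}")
    fish = ref_fish or FishState.reference(c)
    lats, lons = env.lats, env.lons
    LA = np.repeat(lats[:, None], len(lons), axis=1).ravel()
    shape = (len(lats), len(lons))

    months = [m for m in SEASONS[season] if m <= int(env.ds.sizes["month"])]
    acc: dict[str, np.ndarray] = {}
    sst_acc = np.zeros(shape)
    for m in months:
        mid = pd.Timestamp(year=year, month=m, day=15)
        day_h = day_length_hours(LA, np.full(LA.shape, np.datetime64(mid)))
        moon = float(moon_fraction(mid))
        sl = env.ds.sel(month=m)
        sst = sl["sst"].values.ravel()
        out = _chain_predict(models, c, fish, sst, sl["t200"].values.ravel(),
                             sl["o2depth_3p5"].values.ravel(),
                             sl["mesozoo"].values.ravel(),
                             np.full(LA.shape, moon), day_h, coefs=coefs)
        sst_acc += sst.reshape(shape)
        for k, v in out.items():
            acc[k] = acc.get(k, 0.0) + v.reshape(shape)
    nm = len(months)
    for k in acc:
        acc[k] = acc[k] / nm
    sst_mean = sst_acc / nm
    mask = (sst_mean >= c.thermal_min) & (sst_mean <= c.thermal_max)

    ds = xr.Dataset({k: (("lat", "lon"), v) for k, v in acc.items()},
                    coords={"lat": lats, "lon": lons})
    ds["sst"] = (("lat", "lon"), sst_mean)
    return EnergeticsMap(ds=ds, mask=mask, season=season,
                         source_id=env.source_id, period=env.period)


def _weighted_mean(values: np.ndarray, areas: np.ndarray, mask: np.ndarray):
    if not mask.any():
        return None
    w = areas[mask]
    return float(np.sum(values[mask] * w) / np.sum(w))


def habitat_change(map_hist: EnergeticsMap, map_fut: EnergeticsMap,
                   areas: np.ndarray | None = None) -> HabitatChangeSummary:
    """Seasonal habitat-area and area-weighted balance change for one source.

    Area change compares the thermal masks; balance change compares the
    area-weighted mean balance inside each period's own mask, and also inside
    the intersection mask (cells favorable in both periods), the
    "consistently favorable" analysis.  An empty mask yields missing (None)
    weighted means, not zeros.
    """
    if map_hist.ds.sizes != map_fut.ds.sizes:
        raise ValueError("historical and future maps must share a grid")
    if areas is None:
        areas = cell_areas(map_hist.ds["lat"].values, map_hist.ds["lon"].values)
    mh, mf = map_hist.mask, map_fut.mask
    area_h = float(areas[mh].sum())
    area_f = float(areas[mf].sum())
    bh = _weighted_mean(map_hist.ds["balance"].values, areas, mh)
    bf = _weighted_mean(map_fut.ds["balance"].values, areas, mf)
    inter = mh & mf
    bci_h = _weighted_mean(map_hist.ds["balance"].values, areas, inter)
    bci_f = _weighted_mean(map_fut.ds["balance"].values, areas, inter)
    return HabitatChangeSummary(
        season=map_hist.season, source_id=map_hist.source_id,
        area_hist_km2=area_h, area_fut_km2=area_f,
        pct_area_change=100.0 * (area_f - area_h) / area_h if area_h > 0 else np.nan,
        balance_hist=bh, balance_fut=bf,
        balance_change=None if (bh is None or bf is None) else bf - bh,
        balance_change_consistent=None if (bci_h is None or bci_f is None)
        else bci_f - bci_h,
        empty_mask=not (mh.any() and mf.any()),
    )


@dataclass
class EnsembleHabitatSummary:
    """Cross-source mean and t-based 95% CI of the habitat-change metrics."""

    season: str
    n_sources: int
    per_source: pd.DataFrame
    mean: dict = field(default_factory=dict)
    ci_low: dict = field(default_factory=dict)
    ci_high: dict = field(default_factory=dict)
    direction_disagreement: dict = field(default_factory=dict)


def ensemble_summary(summaries: list[HabitatChangeSummary],
                     confidence: float = 0.95) -> EnsembleHabitatSummary:
    """Summarize one season's HabitatChangeSummary list across climate sources.

    Reports the cross-source mean and a t-distribution confidence interval
    (suppressed for a single source) for the area change, percent area
    change, and balance changes, plus a flag per metric when sources disagree
    on the sign of the change.
    """
    if not summaries:
        raise ValueError("no summaries given")
    seasons = {s.season for s in summaries}
    if len(seasons) != 1:
        raise ValueError(f"summaries span multiple seasons {seasons}")
    rows = pd.DataFrame([{
        "source_id": s.source_id,
        "area_change_km2": s.area_change_km2,
        "pct_area_change": s.pct_area_change,
        "balance_change": s.balance_change,
        "balance_change_consistent": s.balance_change_consistent,
    } for s in summaries])
    out = EnsembleHabitatSummary(season=summaries[0].season,
                                 n_sources=len(summaries), per_source=rows)
    for col in ("area_change_km2", "pct_area_change", "balance_change",
                "balance_change_consistent"):
        vals = rows[col].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        mean = float(np.mean(vals))
        out.mean[col] = mean
        if len(vals) >= 2:
            se = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
            tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, df=len(vals) - 1))
            out.ci_low[col] = mean - tcrit * se
            out.ci_high[col] = mean + tcrit * se
        n_pos = int((vals > 0).sum())
        n_neg = int((vals < 0).sum())
        out.direction_disagreement[col] = n_pos > 0 and n_neg > 0
    return out
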