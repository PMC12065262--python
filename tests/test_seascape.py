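"""Tests for astronomy, grid geometry, seascape projection and habitat change."""

import copy

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import energyscape as es
from energyscape.seascape import EnergeticsMap, HabitatChangeSummary
from energyscape.synthetic import SyntheticConfig

from conftest import NOISE_FREE


# ---------------------------------------------------------------------------
# astronomy
# ---------------------------------------------------------------------------

def test_equator_day_length_always_twelve_hours():
    for month in range(1, 13):
        d = np.datetime64(f"2000-{month:02d}-15")
        assert es.day_length_hours(0.0, d) == pytest.approx(12.0, abs=0.15)


def test_solstice_day_length_50N():
    assert es.day_length_hours(50.0, np.datetime64("2000-06-21")) == pytest.approx(
        16.3, abs=0.3)


def test_polar_night_and_day():
    assert es.day_length_hours(80.0, np.datetime64("2000-12-21")) == 0.0
    assert es.day_length_hours(80.0, np.datetime64("2000-06-21")) == 24.0
    with pytest.raises(ValueError):
        es.day_length_hours(95.0, np.datetime64("2000-06-21"))


def test_moon_fraction_synodic_period():
    d1 = np.datetime64("2010-03-01T00:00")
    d2 = d1 + np.timedelta64(int(29.530588 * 24 * 3600), "s")
    f1, f2 = es.moon_fraction(d1), es.moon_fraction(d2)
    assert f1 == pytest.approx(f2, abs=2.0)
    # full range over one cycle
    days = pd.date_range("2010-01-01", periods=30, freq="D").to_numpy()
    f = es.moon_fraction(days)
    assert f.min() < 5.0 and f.max() > 95.0


# ---------------------------------------------------------------------------
# temperature profile and cell areas
# ---------------------------------------------------------------------------

def test_temp_at_depth_surface_is_sst():
    assert es.temp_at_depth(20.0, 14.0, 0.0) == 20.0


def test_temp_at_depth_depth_average_is_t200():
    z = np.linspace(0, 200, 100001)
    prof = es.temp_at_depth(20.0, 14.0, z)
    assert np.trapezoid(prof, z) / 200.0 == pytest.approx(14.0, abs=1e-6)


def test_temp_at_depth_example():
    assert es.temp_at_depth(20.0, 14.0, 200.0) == pytest.approx(8.0)
    assert es.temp_at_depth(20.0, 14.0, 500.0) == pytest.approx(8.0)  # clamped


def test_cell_area_equatorial_one_degree():
    a = es.cell_areas(np.array([0.5]), np.array([0.5, 1.5]))
    assert a[0, 0] == pytest.approx(12364.0, abs=1.0)


def test_cell_area_cosine_latitude():
    a = es.cell_areas(np.array([0.0, 60.0]), np.array([0.5, 1.5]))
    assert a[1, 0] == pytest.approx(0.5 * a[0, 0], rel=0.005)


def test_global_one_degree_area_sums_to_sphere():
    lats = np.arange(-89.5, 90, 1.0)
    lons = np.arange(0.5, 360, 1.0)
    total = es.cell_areas(lats, lons).sum()
    assert total == pytest.approx(4 * np.pi * 6371.0 ** 2, rel=1e-3)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def test_thermal_mask_inclusive_bounds(env, models, constants):
    emap = es.project_energetics(env, models, constants, season="JJA")
    sst = emap.ds["sst"].values
    mask = emap.mask
    assert np.array_equal(mask, (sst >= 11.0) & (sst <= 22.0))


def test_projection_deterministic(env, models, constants):
    a = es.project_energetics(env, models, constants, season="MAM")
    b = es.project_energetics(env, models, constants, season="MAM")
    assert a.ds.identical(b.ds)
    assert np.array_equal(a.mask, b.mask)


def test_projection_balance_consistent_with_accounting(env, models, constants):
    emap = es.project_energetics(env, models, constants, season="JJA")
    bal = es.daily_balance(emap.ds["ingested"].values, emap.ds["cost"].values,
                           constants)
    assert np.allclose(emap.ds["balance"].values, bal)


def test_uniform_fields_give_latitude_only_structure(models, constants):
    """Spatially uniform inputs leave longitude structure flat; only the
    day-length latitude dependence survives."""
    lats = np.arange(30.5, 40.5, 1.0)
    lons = np.arange(180.5, 190.5, 1.0)
    months = np.arange(1, 13)
    import xarray as xr
    shape = (len(months), len(lats), len(lons))
    ds = xr.Dataset({
        "sst": (("month", "lat", "lon"), np.full(shape, 18.0)),
        "t200": (("month", "lat", "lon"), np.full(shape, 14.0)),
        "o2depth_3p5": (("month", "lat", "lon"), np.full(shape, 200.0)),
        "mesozoo": (("month", "lat", "lon"), np.full(shape, 900.0)),
    }, coords={"month": months, "lat": lats, "lon": lons})
    env_u = es.EnvFieldSet(ds=ds, source_id="uniform", period="historical")
    emap = es.project_energetics(env_u, models, constants, season="JJA")
    bal = emap.ds["balance"].values
    assert np.allclose(bal, bal[:, :1])           # constant along longitude
    assert np.ptp(bal) <= np.ptp(bal[:, 0]) + 1e-9


def test_missing_variable_named(env, models, constants):
    broken = es.EnvFieldSet(ds=env.ds.drop_vars("mesozoo"),
                            source_id="x", period="historical")
    with pytest.raises(ValueError, match="mesozoo"):
        es.project_energetics(broken, models, constants, season="JJA")


# ---------------------------------------------------------------------------
# habitat change
# ---------------------------------------------------------------------------

def _toy_map(balance, sst, season="JJA", source="s", period="historical"):
    import xarray as xr
    lats = np.array([10.5, 11.5])
    lons = np.array([0.5])
    ds = xr.Dataset({
        "balance": (("lat", "lon"), np.asarray(balance, dtype=float)),
        "sst": (("lat", "lon"), np.asarray(sst, dtype=float)),
        "ingested": (("lat", "lon"), np.zeros((2, 1))),
        "cost": (("lat", "lon"), np.zeros((2, 1))),
    }, coords={"lat": lats, "lon": lons})
    mask = (ds["sst"].values >= 11.0) & (ds["sst"].values <= 22.0)
    return EnergeticsMap(ds=ds, mask=mask, season=season,
                         source_id=source, period=period)


def test_identical_periods_zero_change(env, models, constants):
    m = es.project_energetics(env, models, constants, season="SON")
    hc = es.habitat_change(m, copy.deepcopy(m))
    assert hc.area_change_km2 == 0.0
    assert hc.pct_area_change == 0.0
    assert hc.balance_change == pytest.approx(0.0, abs=1e-9)


def test_uniform_balance_weighted_mean_identity():
    m1 = _toy_map([[5.0], [5.0]], [[15.0], [15.0]])
    m2 = _toy_map([[5.0], [5.0]], [[15.0], [15.0]], period="future")
    hc = es.habitat_change(m1, m2)
    assert hc.balance_hist == pytest.approx(5.0)
    assert hc.balance_fut == pytest.approx(5.0)


def test_two_cell_weighted_mean_arithmetic():
    """Areas 1 and 3 km2 with balances 10 and 2: weighted mean 4.0."""
    m1 = _toy_map([[10.0], [2.0]], [[15.0], [15.0]])
    m2 = _toy_map([[10.0], [2.0]], [[15.0], [15.0]], period="future")
    areas = np.array([[1.0], [3.0]])
    hc = es.habitat_change(m1, m2, areas=areas)
    assert hc.balance_hist == pytest.approx(4.0)


def test_empty_mask_reported_missing():
    m1 = _toy_map([[1.0], [1.0]], [[30.0], [30.0]])   # all outside envelope
    m2 = _toy_map([[1.0], [1.0]], [[30.0], [30.0]], period="future")
    hc = es.habitat_change(m1, m2)
    assert hc.empty_mask
    assert hc.balance_hist is None and hc.balance_change is None


def test_weighted_mean_bounded_by_field(env, env_future, models, constants):
    mh = es.project_energetics(env, models, constants, season="JJA")
    mf = es.project_energetics(env_future, models, constants, season="JJA")
    hc = es.habitat_change(mh, mf)
    bal = mh.ds["balance"].values[mh.mask]
    assert bal.min() <= hc.balance_hist <= bal.max()


def test_mask_monotone_under_uniform_warming(env, models, constants):
    """Uniform warming moves cells out at the warm edge and in at the cold
    edge; the area change equals cold-edge gain minus warm-edge loss."""
    m = es.project_energetics(env, models, constants, season="JJA")
    sst = m.ds["sst"].values
    delta = 1.0
    new_mask = (sst + delta >= constants.thermal_min) & (sst + delta <= constants.thermal_max)
    gained = new_mask & ~m.mask
    lost = m.mask & ~new_mask
    assert np.all(sst[gained] < constants.thermal_min)        # cold-edge entries
    assert np.all(sst[lost] > constants.thermal_max - delta)  # warm-edge exits
    areas = es.cell_areas(m.ds["lat"].values, m.ds["lon"].values)
    assert areas[new_mask].sum() - areas[m.mask].sum() == pytest.approx(
        areas[gained].sum() - areas[lost].sum(), rel=1e-12)


# ---------------------------------------------------------------------------
# ensemble summary
# ---------------------------------------------------------------------------

def _summary(season, source, dbal, area_h=10.0, area_f=8.0):
    return HabitatChangeSummary(
        season=season, source_id=source, area_hist_km2=area_h, area_fut_km2=area_f,
        pct_area_change=100 * (area_f - area_h) / area_h,
        balance_hist=1.0, balance_fut=1.0 + dbal, balance_change=dbal,
        balance_change_consistent=dbal)


def test_identical_sources_zero_ci_width():
    summaries = [_summary("JJA", s, 5.0) for s in "abcde"]
    es_ = es.ensemble_summary(summaries)
    assert es_.mean["balance_change"] == pytest.approx(5.0)
    assert es_.ci_high["balance_change"] - es_.ci_low["balance_change"] == \
        pytest.approx(0.0, abs=1e-12)


def test_ci_matches_t_distribution_closed_form():
    vals = [1.0, 2.0, 4.0, 4.5, 7.0]
    summaries = [_summary("JJA", f"s{i}", v) for i, v in enumerate(vals)]
    es_ = es.ensemble_summary(summaries)
    mean = np.mean(vals)
    half = stats.t.ppf(0.975, 4) * np.std(vals, ddof=1) / np.sqrt(5)
    assert es_.ci_low["balance_change"] == pytest.approx(mean - half, abs=1e-9)
    assert es_.ci_high["balance_change"] == pytest.approx(mean + half, abs=1e-9)


def test_direction_disagreement_flagged():
    vals = [1.0, 2.0, 0.5, -1.0, -0.2]
    summaries = [_summary("JJA", f"s{i}", v) for i, v in enumerate(vals)]
    es_ = es.ensemble_summary(summaries)
    assert es_.direction_disagreement["balance_change"]
    agree = [_summary("JJA", f"s{i}", v) for i, v in enumerate([1.0, 2.0, 0.5])]
    assert not es.ensemble_summary(agree).direction_disagreement["balance_change"]


def test_single_source_suppresses_ci():
    es_ = es.ensemble_summary([_summary("JJA", "only", 3.0)])
    assert es_.mean["balance_change"] == 3.0
    assert "balance_change" not in es_.ci_low


def test_mixed_seasons_rejected():
    with pytest.raises(ValueError, match="season"):
        es.ensemble_summary([_summary("JJA", "a", 1.0), _summary("DJF", "b", 1.0)])
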