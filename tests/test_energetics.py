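"""Tests for the accounting arithmetic and the four fitted models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import energyscape as es
from energyscape.energetics import predict_ingested
from energyscape.synthetic import SyntheticConfig

from conftest import NOISE_FREE


# ---------------------------------------------------------------------------
# conversions and accounting
# ---------------------------------------------------------------------------

def test_oxycalorific_unit_conversion():
    """1 mg O2/kg/h for 1 kg over 1 h is 13.59 J."""
    assert es.mo2_to_kj(1, 1, 1) == pytest.approx(0.01359, abs=1e-12)


def test_mo2_to_kj_hand_arithmetic():
    assert es.mo2_to_kj(100, 11, 24) == pytest.approx(358.776, abs=1e-9)
    assert es.mo2_to_kj(0, 5, 24) == 0.0


def test_mo2_to_kj_rejects_negative():
    with pytest.raises(ValueError):
        es.mo2_to_kj(-1, 1, 1)


@settings(max_examples=50, derandomize=True)
@given(mo2=st.floats(0, 1e3), w=st.floats(0, 50), h=st.floats(0, 24))
def test_mo2_to_kj_bilinear(mo2, w, h):
    base = es.mo2_to_kj(mo2, w, h)
    assert es.mo2_to_kj(2 * mo2, w, h) == pytest.approx(2 * base, rel=1e-12, abs=1e-12)
    assert es.mo2_to_kj(mo2, w, 2 * h) == pytest.approx(2 * base, rel=1e-12, abs=1e-12)


def test_daily_balance_examples():
    assert es.daily_balance(1000, 100) == pytest.approx(538.0, abs=1e-9)
    assert es.daily_balance(0, 0) == 0.0
    assert es.daily_balance(1000, 638) == pytest.approx(0.0, abs=1e-9)


@settings(max_examples=50, derandomize=True)
@given(ing=st.floats(0, 1e4), cost=st.floats(0, 1e4), d=st.floats(1, 100))
def test_daily_balance_linearity(ing, cost, d):
    """Slope 0.638 in ingested energy, slope -1 in movement cost."""
    b = es.daily_balance(ing, cost)
    assert es.daily_balance(ing + d, cost) - b == pytest.approx(0.638 * d, rel=1e-9)
    assert es.daily_balance(ing, cost + d) - b == pytest.approx(-d, rel=1e-9)


def test_constants_invariants():
    with pytest.raises(ValueError):
        es.EnergeticsConstants(sda_loss=0.6, egestion_loss=0.5)
    with pytest.raises(ValueError):
        es.EnergeticsConstants(thermal_min=25.0, thermal_max=11.0)


def test_length_weight_reference_fish():
    """Default allometry puts an 80 cm albacore at 11 +- 0.5 kg."""
    assert 10.5 <= es.length_to_weight(80.0) <= 11.5


def test_interpolate_length():
    assert es.interpolate_length("2011-01-01", 70.0, "2011-03-02", 80.0,
                                 "2011-01-31") == pytest.approx(75.0)
    assert es.interpolate_length("2011-01-01", 70.0, "2011-03-02", 80.0,
                                 "2011-01-01") == 70.0
    with pytest.raises(ValueError, match="outside"):
        es.interpolate_length("2011-01-01", 70.0, "2011-03-02", 80.0, "2011-06-01")


# ---------------------------------------------------------------------------
# model 2 (metabolic cost)
# ---------------------------------------------------------------------------

def test_cost_model_noise_free_recovery(quiet_world):
    """Noise-free respirometry surface is reproduced within 1% of its range."""
    resp = quiet_world["resp"]
    m = quiet_world["models"].cost
    pred = m.predict(resp.df)
    truth = resp.df["mo2"].to_numpy()
    span = truth.max() - truth.min()
    assert np.abs(pred - truth).max() < 0.01 * span


def test_cost_model_monotone_in_speed(quiet_world):
    m = quiet_world["models"].cost
    lo = m.predict(pd.DataFrame({"temperature_C": [18.0], "speed_bls": [1.0]}))
    hi = m.predict(pd.DataFrame({"temperature_C": [18.0], "speed_bls": [2.0]}))
    assert hi[0] > lo[0]


def test_cost_model_rejects_one_dimensional_data():
    df = pd.DataFrame({"temperature_C": np.linspace(10, 25, 60),
                       "speed_bls": np.full(60, 1.5),
                       "mo2": np.linspace(100, 300, 60)})
    with pytest.raises(ValueError, match="speed"):
        es.fit_cost_model(df)


def test_cost_model_requires_enough_rows():
    df = pd.DataFrame({"temperature_C": [10, 20], "speed_bls": [1, 2], "mo2": [1, 2]})
    with pytest.raises(ValueError, match="50"):
        es.fit_cost_model(df)


# ---------------------------------------------------------------------------
# model 4 (ingestion)
# ---------------------------------------------------------------------------

def test_ingestion_model_noise_free_recovery(quiet_world):
    trials = quiet_world["trials"]
    m = quiet_world["models"].ingestion
    pred = m.predict(trials.df)
    truth = trials.df["kj_ingested"].to_numpy()
    span = truth.max() - truth.min()
    assert np.sqrt(np.mean((pred - truth) ** 2)) < 0.01 * span


def test_ingestion_zero_hif_near_zero(quiet_world):
    trials = quiet_world["trials"]
    m = quiet_world["models"].ingestion
    span = trials.df["kj_ingested"].max() - trials.df["kj_ingested"].min()
    val = predict_ingested(m, 0.0, 17.0, 70.0)[0]
    assert 0.0 <= val < 0.01 * span


def test_ingestion_prediction_floored_at_zero(models):
    vals = predict_ingested(models.ingestion, np.zeros(5), 14.0, 70.0)
    assert np.all(vals >= 0.0)


# ---------------------------------------------------------------------------
# models 1a/1b (diel depth) and 3 (HIF)
# ---------------------------------------------------------------------------

def test_day_depth_partial_response_monotone_in_o2depth(quiet_world):
    """Generator day depth rises with the O2-3.5 depth; the fitted partial
    response is monotone increasing and accurate to a few metres."""
    m = quiet_world["models"].depth_day
    lo, hi = m.ranges["o2depth_3p5"]
    grid = np.linspace(lo, hi, 100)
    f = m.partial_response("o2depth_3p5", grid)
    assert np.all(np.diff(f) > -0.25)             # monotone up to basis wiggle
    assert f[-1] - f[0] > 10.0
    pred = m.predict(pd.DataFrame({
        "t200": np.full(100, np.mean(m.ranges["t200"])),
        "moon_pct": np.full(100, 50.0), "o2depth_3p5": grid}))
    truth = np.clip(0.45 * grid, 20.0, 190.0)
    rmse = np.sqrt(np.mean(((pred - pred.mean()) - (truth - truth.mean())) ** 2))
    assert rmse < 5.0


def test_night_depth_flat_moon_response(quiet_world):
    """Generator night depth ignores the moon; the fitted moon partial
    response is flat within its pointwise confidence band."""
    m = quiet_world["models"].depth_night
    lo, hi = m.ranges["moon_pct"]
    grid = np.linspace(lo, hi, 50)
    f = m.partial_response("moon_pct", grid)
    # pointwise band from the coefficient covariance
    idx = 1
    for ts in m.term_states:
        if ts.names == ["moon_pct"]:
            break
        idx += ts.n_coef
    B = ts.design(pd.DataFrame({"moon_pct": grid}))
    V = m.cov[idx:idx + ts.n_coef, idx:idx + ts.n_coef]
    se = np.sqrt(np.maximum(np.sum((B @ V) * B, axis=1), 0.0))
    assert np.all(np.abs(f) <= 2.0 * se + 1e-6)


def test_constant_depth_fish_gives_flat_model():
    c = SyntheticConfig(seed=9, n_fish=1, deployment_days=30,
                        noise_sd=dict(NOISE_FREE))
    tag = es.generate_tag_record(c, feeding_schedule=None)   # env=None: fixed depths
    env = es.generate_env_fields(c, "historical", "obs")
    day_df, night_df = es.assemble_depth_training([tag], env)
    m_day, m_night = es.fit_depth_models(day_df, night_df)
    assert m_day.deviance_explained < 1.0
    assert np.allclose(m_day.predict(day_df), day_df["depth_m"].mean(), atol=0.5)


def test_hif_model_recovers_generator_relationship(quiet_world):
    """Model 3 trained on noise-free truth reproduces the generating linear
    foraging relationship within 1% of the response range."""
    m = quiet_world["models"].hif
    coeffs = quiet_world["hif_coeffs"]
    env = quiet_world["env"]
    tags = quiet_world["tags"]
    mz_lo, mz_hi = m.ranges["mesozoo"]
    grid = np.linspace(mz_lo, mz_hi, 50)
    L = float(np.mean([t.daily["length_cm"].mean() for t in tags]))
    pred = m.predict(pd.DataFrame({
        "mesozoo": grid, "length_cm": np.full(50, L),
        "day_length_h": np.full(50, 13.0)}))
    truth = coeffs["mz"] * grid + coeffs["dl"] * (13.0 - 12.0)
    span = truth.max() - truth.min()
    assert np.sqrt(np.mean((pred - truth) ** 2)) < 0.05 * span + 0.05


def test_hif_model_flat_length_response(quiet_world):
    """Generator HIF does not depend on fish length; the length partial
    response stays within its confidence band."""
    m = quiet_world["models"].hif
    lo, hi = m.ranges["length_cm"]
    grid = np.linspace(lo, hi, 40)
    f = m.partial_response("length_cm", grid)
    idx = 1
    for ts in m.term_states:
        if ts.names == ["length_cm"]:
            break
        idx += ts.n_coef
    B = ts.design(pd.DataFrame({"length_cm": grid}))
    V = m.cov[idx:idx + ts.n_coef, idx:idx + ts.n_coef]
    se = np.sqrt(np.maximum(np.sum((B @ V) * B, axis=1), 0.0))
    assert np.all(np.abs(f) <= 3.0 * se + 0.05)


def test_noisy_fits_within_three_se(models, env, tags):
    """With the stated noise levels, fitted-model predictions bracket the
    generator relationships within ~3 standard errors (checked for the cost
    model against its parametric surface)."""
    cfg_n = SyntheticConfig(seed=11)
    resp = es.generate_respirometry(cfg_n)
    m = models.cost
    grid = pd.DataFrame({
        "temperature_C": np.linspace(11, 24, 30),
        "speed_bls": np.linspace(0.6, 2.9, 30)})
    pred = m.predict(grid)
    truth = resp.surface(grid["temperature_C"], grid["speed_bls"])
    X = m.design(grid)
    se = np.sqrt(np.maximum(np.sum((X @ m.cov) * X, axis=1), 0.0))
    frac_inside = np.mean(np.abs(pred - truth) <= 3.0 * se)
    assert frac_inside >= 0.9
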