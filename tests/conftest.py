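"""Shared fixtures: a seeded synthetic world and a fitted model chain.

Session-scoped so the (few-second) generation and fitting cost is paid once.
``quiet_world`` is the noise-free variant on which every downstream quantity
is analytically composable from the generator surfaces.
"""

import numpy as np
import pandas as pd
import pytest

import energyscape as es
from energyscape.astro import day_length_hours
from energyscape.hif import (
    compute_daily_hif,
    daily_hif_frame,
    estimate_baseline,
    solar_offset_hours,
)
from energyscape.pipeline import assemble_depth_training, assemble_hif_training
from energyscape.synthetic import SyntheticConfig

NOISE_FREE = {"sst": 0.0, "t200": 0.0, "o2depth_3p5": 0.0, "mesozoo": 0.0,
              "body_temp": 0.0, "depth": 0.0, "ambient": 0.0,
              "mo2": 0.0, "kj": 0.0}


@pytest.fixture(scope="session")
def cfg():
    return SyntheticConfig(seed=11, n_fish=3, deployment_days=90, resolution=2.0)


@pytest.fixture(scope="session")
def constants():
    return es.EnergeticsConstants()


@pytest.fixture(scope="session")
def env(cfg):
    return es.generate_env_fields(cfg, "historical", "obs")


@pytest.fixture(scope="session")
def env_future(cfg):
    return es.generate_env_fields(cfg, "future", "obs")


@pytest.fixture(scope="session")
def tags(cfg, env):
    return es.generate_tag_records(cfg, env=env, feeding_schedule="env")


@pytest.fixture(scope="session")
def hif_frames(tags):
    out = {}
    for tag in tags:
        baseline = estimate_baseline(tag.minute)
        out[tag.fish_id] = daily_hif_frame(compute_daily_hif(
            tag.minute, baseline,
            lon_offset_hours=solar_offset_hours(tag.mean_lon)))
    return out


def _fit_chain(cfg, env, tags, hif_frames):
    day_df, night_df = assemble_depth_training(tags, env)
    m_day, m_night = es.fit_depth_models(day_df, night_df)
    m_cost = es.fit_cost_model(es.generate_respirometry(cfg))
    hif_df = assemble_hif_training(tags, env, hif_frames)
    m_hif = es.fit_hif_model(hif_df)
    m_ing = es.fit_ingestion_model(es.generate_feeding_trials(cfg))
    return es.ModelChain(m_day, m_night, m_cost, m_hif, m_ing)


@pytest.fixture(scope="session")
def models(cfg, env, tags, hif_frames):
    return _fit_chain(cfg, env, tags, hif_frames)


@pytest.fixture(scope="session")
def quiet_world():
    """Noise-free world: generators, truth-trained chain, and the generator
    parameter stores needed to hand-compose expected values."""
    qcfg = SyntheticConfig(seed=23, n_fish=3, deployment_days=60,
                           resolution=2.0, noise_sd=dict(NOISE_FREE))
    env = es.generate_env_fields(qcfg, "historical", "obs")
    env_fut = es.generate_env_fields(qcfg, "future", "obs")
    tags = es.generate_tag_records(qcfg, env=env, feeding_schedule="env")
    day_df, night_df = assemble_depth_training(tags, env)
    m_day, m_night = es.fit_depth_models(day_df, night_df)
    resp = es.generate_respirometry(qcfg)
    trials = es.generate_feeding_trials(qcfg)
    m_cost = es.fit_cost_model(resp)
    m_ing = es.fit_ingestion_model(trials)
    # model 3 trained directly on the generator's per-day HIF truth
    rows = []
    for tag in tags:
        dates = pd.to_datetime(tag.daily["date"])
        doy = dates.dt.dayofyear.to_numpy()
        mz = env.sample("mesozoo", tag.daily["lat"].to_numpy(),
                        tag.daily["lon"].to_numpy(), (doy % 365) * 12.0 / 365.0)
        dl = day_length_hours(tag.daily["lat"].to_numpy(), dates.to_numpy())
        hif_truth = tag.truth["daily_hif"].to_numpy()
        for i in range(len(dates)):
            rows.append({"hif": hif_truth[i], "mesozoo": mz[i],
                         "length_cm": float(tag.daily["length_cm"].iloc[i]),
                         "day_length_h": dl[i]})
    m_hif = es.fit_hif_model(pd.DataFrame(rows))
    chain = es.ModelChain(m_day, m_night, m_cost, m_hif, m_ing)
    return {"cfg": qcfg, "env": env, "env_fut": env_fut, "tags": tags,
            "models": chain, "resp": resp, "trials": trials,
            "hif_coeffs": tags[0].truth["hif_coeffs"]}
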