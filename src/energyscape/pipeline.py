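"""End-to-end pipeline: synth -> fit -> hif -> track -> project -> uncertainty.

Runs the whole framework at desk scale on synthetic inputs, writing
versioned stage outputs plus a manifest (seeds, content hashes, clamp and
fallback counters) so a rerun with the same configuration reproduces
identical artifacts and a deleted intermediate triggers regeneration of
only the downstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .astro import day_length_hours, moon_fraction
from .energetics import (
    EnergeticsConstants,
    FishState,
    ModelChain,
    fit_cost_model,
    fit_depth_models,
    fit_hif_model,
    fit_ingestion_model,
)
from .hif import compute_daily_hif, daily_hif_frame, estimate_baseline, solar_offset_hours
from .seascape import (
    SEASONS,
    EnergeticsMap,
    cell_areas,
    ensemble_summary,
    habitat_change,
    project_energetics,
)
from .synthetic import (
    EnvFieldSet,
    SyntheticConfig,
    generate_env_fields,
    generate_feeding_trials,
    generate_respirometry,
    generate_tag_records,
)
from .track import daily_tag_summaries, reexperience_track, track_daily_energetics
from .uncertainty import EnsembleSpec, build_ensemble, slot_sweep, variance_attribution

logger = logging.getLogger("energyscape")

__all__ = ["RunConfig", "run_all", "assemble_depth_training", "assemble_hif_training",
           "DEFAULT_SOURCES"]

# labels only; the synthetic generator gives each source its own perturbation
DEFAULT_SOURCES = ("esm-a", "esm-b", "esm-c", "esm-d", "esm-e")

# execution order; HIF extraction precedes fitting because the foraging
# model (model 3) trains on the extracted daily HIF
STAGES = ("synth", "hif", "fit", "track", "project", "uncertainty")


@dataclass
class RunConfig:
    outdir: str = "runs/toy"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    constants: EnergeticsConstants = field(default_factory=EnergeticsConstants)
    ensemble: EnsembleSpec = field(default_factory=lambda: EnsembleSpec(k_per_model=3))
    sources: tuple[str, ...] = DEFAULT_SOURCES
    seasons: tuple[str, ...] = tuple(SEASONS)
    scenario_label: str = "SSP2-4.5"
    uncertainty_season: str = "JJA"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        if "synthetic" in raw:
            kw["synthetic"] = SyntheticConfig(**raw.pop("synthetic"))
        if "energetics" in raw:
            kw["constants"] = EnergeticsConstants(**raw.pop("energetics"))
        if "ensemble" in raw:
            kw["ensemble"] = EnsembleSpec(**raw.pop("ensemble"))
        for key in ("outdir", "sources", "seasons", "scenario_label",
                    "uncertainty_season"):
            if key in raw:
                kw[key] = raw.pop(key)
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        if isinstance(kw.get("sources"), list):
            kw["sources"] = tuple(kw["sources"])
        if isinstance(kw.get("seasons"), list):
            kw["seasons"] = tuple(kw["seasons"])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        doc = {
            "outdir": self.outdir,
            "synthetic": dataclasses.asdict(self.synthetic),
            "energetics": dataclasses.asdict(self.constants),
            "ensemble": {"k_per_model": self.ensemble.k_per_model,
                         "seed": self.ensemble.seed,
                         "percentiles": list(self.ensemble.percentiles)},
            "sources": list(self.sources),
            "seasons": list(self.seasons),
            "scenario_label": self.scenario_label,
            "uncertainty_season": self.uncertainty_season,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# training-data assembly
# ---------------------------------------------------------------------------

def assemble_depth_training(tags, env: EnvFieldSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Day and night depth-model frames: per fish-day mean depths matched to
    T200, moon illumination and O2-3.5 depth at the daily position."""
    day_rows, night_rows = [], []
    for tag in tags:
        summ = daily_tag_summaries(tag).set_index("date")
        daily = tag.daily
        dates = pd.to_datetime(daily["date"])
        doy = dates.dt.dayofyear.to_numpy()
        mf = (doy % 365) * 12.0 / 365.0
        t200 = env.sample("t200", daily["lat"].to_numpy(), daily["lon"].to_numpy(), mf)
        o2d = env.sample("o2depth_3p5", daily["lat"].to_numpy(),
                         daily["lon"].to_numpy(), mf)
        moon = moon_fraction(dates.to_numpy())
        for i, d in enumerate(dates):
            row = summ.loc[d] if d in summ.index else None
            if row is None:
                continue
            common = {"t200": t200[i], "moon_pct": moon[i], "o2depth_3p5": o2d[i]}
            if np.isfinite(row["day_depth_m"]):
                day_rows.append({"depth_m": row["day_depth_m"], **common})
            if np.isfinite(row["night_depth_m"]):
                night_rows.append({"depth_m": row["night_depth_m"], **common})
    return pd.DataFrame(day_rows), pd.DataFrame(night_rows)


def assemble_hif_training(tags, env: EnvFieldSet,
                          hif_frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Foraging-model frame: daily HIF matched to mesozooplankton biomass,
    interpolated fish length and day length."""
    rows = []
    for tag in tags:
        hf = hif_frames[tag.fish_id].set_index("date")
        daily = tag.daily
        dates = pd.to_datetime(daily["date"])
        doy = dates.dt.dayofyear.to_numpy()
        mz = env.sample("mesozoo", daily["lat"].to_numpy(), daily["lon"].to_numpy(),
                        (doy % 365) * 12.0 / 365.0)
        dl = day_length_hours(daily["lat"].to_numpy(), dates.to_numpy())
        for i, d in enumerate(dates):
            if d not in hf.index:
                continue
            rec = hf.loc[d]
            if rec.get("flagged", False) or not np.isfinite(rec["hif"]):
                continue
            rows.append({"hif": max(float(rec["hif"]), 0.0), "mesozoo": mz[i],
                         "length_cm": float(daily["length_cm"].iloc[i]),
                         "day_length_h": dl[i]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path):
        self.path = path
        self.doc = {"stages": {}}
        if os.path.exists(path):
            with open(path) as fh:
                self.doc = json.load(fh)

    def record(self, stage, inputs, outputs, **extra):
        self.doc["stages"][stage] = {
            "inputs": sorted(map(str, inputs)),
            "outputs": {str(p): _sha256(p) for p in sorted(map(str, outputs))},
            **extra,
        }
        with open(self.path, "w") as fh:
            json.dump(self.doc, fh, indent=1, sort_keys=True)

    def outputs_exist(self, stage) -> bool:
        st = self.doc["stages"].get(stage)
        return bool(st) and all(os.path.exists(p) for p in st["outputs"])


def run_all(cfg: RunConfig, force: bool = False, until: str | None = None) -> dict:
    """Execute the stages in order (synth, hif, fit, track, project,
    uncertainty), skipping stages whose recorded outputs all still exist
    (delete an intermediate to regenerate it and everything downstream).
    ``until`` stops after the named stage.  Returns a dict of headline
    results."""
    if until is not None and until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    out = cfg.outdir
    os.makedirs(out, exist_ok=True)
    for sub in ("env", "tags", "lab", "models", "hif", "track", "maps", "uncertainty"):
        os.makedirs(os.path.join(out, sub), exist_ok=True)
    manifest = _Manifest(os.path.join(out, "manifest.json"))
    cfg.to_yaml(os.path.join(out, "config.yaml"))
    results: dict = {}
    downstream_dirty = force

    # ---- synth -----------------------------------------------------------
    env_paths = {(s, p): os.path.join(out, "env", f"{s}_{p}.nc")
                 for s in cfg.sources for p in ("historical", "future")}
    obs_path = os.path.join(out, "env", "obs_historical.nc")
    stage_outputs = [obs_path, *env_paths.values(),
                     os.path.join(out, "lab", "respirometry.csv"),
                     os.path.join(out, "lab", "feeding_trials.csv")]
    if downstream_dirty or not manifest.outputs_exist("synth"):
        downstream_dirty = True
        generate_env_fields(cfg.synthetic, "historical", "obs").to_netcdf(obs_path)
        for (s, p), path in env_paths.items():
            generate_env_fields(cfg.synthetic, p, s).to_netcdf(path)
        resp = generate_respirometry(cfg.synthetic)
        trials = generate_feeding_trials(cfg.synthetic)
        resp.df.to_csv(os.path.join(out, "lab", "respirometry.csv"), index=False)
        trials.df.to_csv(os.path.join(out, "lab", "feeding_trials.csv"), index=False)
        with open(os.path.join(out, "lab", "generator_params.json"), "w") as fh:
            json.dump({"respirometry": resp.params, "feeding_trials": trials.params}, fh)
        obs_env = EnvFieldSet.from_netcdf(obs_path)
        tags = generate_tag_records(cfg.synthetic, env=obs_env, feeding_schedule="env")
        tag_paths = []
        for tag in tags:
            tag_paths += list(tag.to_csv(os.path.join(out, "tags")))
        manifest.record("synth", [], stage_outputs + tag_paths,
                        seed=cfg.synthetic.seed)
    else:
        logger.info("synth outputs present; skipping")
        obs_env = EnvFieldSet.from_netcdf(obs_path)
        from .synthetic import TagRecord
        tags = [TagRecord.from_csv(
            os.path.join(out, "tags", f"fish{i}_daily.csv"),
            os.path.join(out, "tags", f"fish{i}_minute.csv"),
            fish_id=f"fish{i}") for i in range(cfg.synthetic.n_fish)]
    # in-memory regeneration keeps truth stores available even when loading CSVs
    if not tags[0].truth:
        tags = generate_tag_records(cfg.synthetic, env=obs_env, feeding_schedule="env")
    if until == "synth":
        return results

    # ---- hif -------------------------------------------------------------
    hif_paths = {t.fish_id: os.path.join(out, "hif", f"{t.fish_id}_hif.csv")
                 for t in tags}
    if downstream_dirty or not manifest.outputs_exist("hif"):
        downstream_dirty = True
        for tag in tags:
            baseline = estimate_baseline(tag.minute)
            frame = daily_hif_frame(compute_daily_hif(
                tag.minute, baseline,
                lon_offset_hours=solar_offset_hours(tag.mean_lon)))
            frame.to_csv(hif_paths[tag.fish_id], index=False)
        manifest.record("hif", [obs_path], list(hif_paths.values()))
    hif_frames = {fid: pd.read_csv(p, parse_dates=["date"])
                  for fid, p in hif_paths.items()}
    if until == "hif":
        return results

    # ---- fit -------------------------------------------------------------
    model_dir = os.path.join(out, "models")
    model_paths = [os.path.join(model_dir, f"{n}.json")
                   for n in ("depth_day", "depth_night", "cost", "hif", "ingestion")]
    if downstream_dirty or not manifest.outputs_exist("fit"):
        downstream_dirty = True
        day_df, night_df = assemble_depth_training(tags, obs_env)
        m_day, m_night = fit_depth_models(day_df, night_df)
        resp_df = pd.read_csv(os.path.join(out, "lab", "respirometry.csv"))
        trials_df = pd.read_csv(os.path.join(out, "lab", "feeding_trials.csv"))
        m_cost = fit_cost_model(resp_df)
        hif_df = assemble_hif_training(tags, obs_env, hif_frames)
        m_hif = fit_hif_model(hif_df)
        m_ing = fit_ingestion_model(trials_df)
        models = ModelChain(m_day, m_night, m_cost, m_hif, m_ing)
        models.to_json_dir(model_dir)
        manifest.record(
            "fit", [obs_path] + list(hif_paths.values()), model_paths,
            deviance_explained={
                "depth_day": m_day.deviance_explained,
                "depth_night": m_night.deviance_explained,
                "cost": m_cost.deviance_explained,
                "hif": m_hif.deviance_explained,
                "ingestion": m_ing.deviance_explained,
            })
    models = ModelChain.from_json_dir(model_dir)
    results["deviance_explained"] = {
        n: getattr(models, n).deviance_explained
        for n in ("depth_day", "depth_night", "cost", "hif", "ingestion")}
    if until == "fit":
        return results

    # ---- track -----------------------------------------------------------
    track_paths = [os.path.join(out, "track", f"{t.fish_id}_daily.csv") for t in tags]
    reexp_paths = [os.path.join(out, "track", f"{t.fish_id}_reexperience.csv")
                   for t in tags]
    if downstream_dirty or not manifest.outputs_exist("track"):
        downstream_dirty = True
        env_h = EnvFieldSet.from_netcdf(env_paths[(cfg.sources[0], "historical")])
        env_f = EnvFieldSet.from_netcdf(env_paths[(cfg.sources[0], "future")])
        for tag, tp, rp in zip(tags, track_paths, reexp_paths):
            te = track_daily_energetics(tag, models, cfg.constants,
                                        daily_hif=hif_frames[tag.fish_id])
            te.to_csv(tp, index=False)
            reexperience_track(tag, env_h, env_f, models, cfg.constants).to_csv(
                rp, index=False)
        manifest.record("track", model_paths, track_paths + reexp_paths)
    track_frames = [pd.read_csv(p, parse_dates=["date"]) for p in track_paths]
    all_track = pd.concat(track_frames)
    results["track_median_balance_kj"] = float(all_track["balance_kj"].median())
    results["track_median_ingested_kj_per_kg"] = float(
        (all_track["ingested_kj"] / all_track["weight_kg"]).median())
    if until == "track":
        return results

    # ---- project ---------------------------------------------------------
    summary_path = os.path.join(out, "maps", "habitat_change.csv")
    ens_path = os.path.join(out, "maps", "ensemble_summary.json")
    if downstream_dirty or not manifest.outputs_exist("project"):
        downstream_dirty = True
        rows = []
        ens_doc = {}
        for season in cfg.seasons:
            season_summaries = []
            for s in cfg.sources:
                env_h = EnvFieldSet.from_netcdf(env_paths[(s, "historical")])
                env_f = EnvFieldSet.from_netcdf(env_paths[(s, "future")])
                mh = project_energetics(env_h, models, cfg.constants, season=season)
                mf_ = project_energetics(env_f, models, cfg.constants, season=season)
                hc = habitat_change(mh, mf_)
                season_summaries.append(hc)
                rows.append(dataclasses.asdict(hc))
                if s == cfg.sources[0]:
                    mh.to_netcdf(os.path.join(
                        out, "maps", f"{s}_{season}_historical.nc"))
                    mf_.to_netcdf(os.path.join(out, "maps", f"{s}_{season}_future.nc"))
            es = ensemble_summary(season_summaries)
            ens_doc[season] = {
                "mean": es.mean, "ci_low": es.ci_low, "ci_high": es.ci_high,
                "direction_disagreement": es.direction_disagreement,
            }
        pd.DataFrame(rows).to_csv(summary_path, index=False)
        with open(ens_path, "w") as fh:
            json.dump(ens_doc, fh, indent=1, sort_keys=True)
        manifest.record("project", model_paths + list(map(str, env_paths.values())),
                        [summary_path, ens_path], scenario=cfg.scenario_label)
    with open(ens_path) as fh:
        results["habitat_change"] = json.load(fh)
    if until == "project":
        return results

    # ---- uncertainty -----------------------------------------------------
    attr_path = os.path.join(out, "uncertainty", "attribution.csv")
    if downstream_dirty or not manifest.outputs_exist("uncertainty"):
        season = cfg.uncertainty_season
        env_h = EnvFieldSet.from_netcdf(env_paths[(cfg.sources[0], "historical")])
        env_f = EnvFieldSet.from_netcdf(env_paths[(cfg.sources[0], "future")])
        areas = cell_areas(env_h.lats, env_h.lons)

        def evaluate(coefs) -> float:
            mh = project_energetics(env_h, models, cfg.constants,
                                    season=season, coefs=coefs)
            mf_ = project_energetics(env_f, models, cfg.constants,
                                     season=season, coefs=coefs)
            hc = habitat_change(mh, mf_, areas)
            return np.nan if hc.balance_change is None else hc.balance_change

        sweeps = slot_sweep(models, cfg.ensemble, evaluate)
        hc_df = pd.read_csv(summary_path)
        src_vals = hc_df.loc[hc_df["season"] == season, "balance_change"].to_numpy()
        sweeps["climate_source"] = src_vals
        attr = variance_attribution(sweeps)
        attr.to_csv(attr_path, index=False)
        manifest.record("uncertainty", model_paths + [summary_path], [attr_path],
                        k_per_model=cfg.ensemble.k_per_model,
                        ensemble_size=cfg.ensemble.k_per_model ** 4)
    results["attribution"] = pd.read_csv(attr_path).to_dict("records")
    results["ensemble_size"] = len(build_ensemble(models, cfg.ensemble))
    return results
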