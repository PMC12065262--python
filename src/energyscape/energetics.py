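"""The four chained biological models and the fixed energy-accounting rules.

Model 1a/1b: diel depth (m) ~ s(T200) + s(moon %) + s(O2-3.5 depth), day and
night fit separately.  Model 2: metabolic movement cost (mg O2 kg-1 h-1) ~
te(temperature, swimming speed).  Model 3: daily Heat Increment of Feeding
(C*hour) ~ s(mesozooplankton) + s(fork length) + s(day length).  Model 4:
energy ingested (kJ) ~ s(HIF) + s(temperature) + s(% finfish in diet).

Accounting: metabolic cost converts to kJ at 13.59 J per mg O2; the daily
balance is kJ ingested minus fixed fractional losses to specific dynamic
action (9.2%) and excretion/egestion (27%) minus movement cost.  Swimming
speed is fixed at 2 body lengths/s by day and 1 by night; the gridded
projections use a reference fish of 80 cm fork length and 11 kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam import SmoothModel, SmoothTerm, TensorTerm, fit_gam

__all__ = [
    "EnergeticsConstants",
    "FishState",
    "mo2_to_kj",
    "daily_balance",
    "length_to_weight",
    "interpolate_length",
    "fit_depth_models",
    "fit_cost_model",
    "fit_hif_model",
    "fit_ingestion_model",
]


@dataclass(frozen=True)
class EnergeticsConstants:
    """Fixed constants of the energy-accounting chain.

    oxycal converts oxygen consumption to energy; sda_loss and egestion_loss
    are fractions of ingested energy lost to specific dynamic action and to
    excretion/egestion; the diel swimming speeds, reference fish, thermal
    envelope and hypoxia threshold are the values the projections assume.
    The length-weight coefficients (W = a * L^b, cm -> kg) are calibrated so
    an 80 cm fish weighs 11.0 kg; they are package defaults, not literature
    values.
    """

    oxycal: float = 13.59            # J per mg O2
    sda_loss: float = 0.092          # fraction of ingested kJ
    egestion_loss: float = 0.27      # fraction of ingested kJ
    speed_day: float = 2.0           # BL s-1
    speed_night: float = 1.0         # BL s-1
    pct_finfish_default: float = 70.0
    ref_length: float = 80.0         # cm fork length
    ref_weight: float = 11.0         # kg
    thermal_min: float = 11.0        # C (inclusive)
    thermal_max: float = 22.0        # C (inclusive)
    o2_threshold: float = 3.5        # ml L-1
    lw_a: float = 11.0 / 80.0 ** 3.05
    lw_b: float = 3.05

    def __post_init__(self) -> None:
        if not (0 <= self.sda_loss < 1 and 0 <= self.egestion_loss < 1):
            raise ValueError("loss fractions must be in [0, 1)")
        if self.sda_loss + self.egestion_loss >= 1:
            raise ValueError("total fractional losses must be < 1")
        if self.thermal_min >= self.thermal_max:
            raise ValueError("thermal_min must be < thermal_max")


@dataclass
class FishState:
    """Reference fish for gridded projections."""

    length: float                    # cm fork length
    weight: float                    # kg

    def __post_init__(self) -> None:
        if self.length <= 0 or self.weight <= 0:
            raise ValueError("length and weight must be positive")

    @classmethod
    def reference(cls, c: EnergeticsConstants) -> "FishState":
        return cls(length=c.ref_length, weight=c.ref_weight)


# ---------------------------------------------------------------------------
# accounting arithmetic
# ---------------------------------------------------------------------------

def mo2_to_kj(mo2, weight, hours, c: EnergeticsConstants | None = None):
    """Oxygen consumption (mg O2 kg-1 h-1) -> energy (kJ).

    kJ = mo2 * weight * hours * oxycal / 1000, so mo2_to_kj(1, 1, 1) is
    0.01359 kJ = 13.59 J.
    """
    c = c or EnergeticsConstants()
    mo2 = np.asarray(mo2, dtype=float)
    if np.any(mo2 < 0) or np.any(np.asarray(weight, dtype=float) < 0) \
            or np.any(np.asarray(hours, dtype=float) < 0):
        raise ValueError("mo2, weight and hours must be >= 0")
    out = mo2 * np.asarray(weight, dtype=float) * np.asarray(hours, dtype=float) \
        * c.oxycal / 1000.0
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def daily_balance(ingested, movement_cost, c: EnergeticsConstants | None = None):
    """Daily energy balance (kJ): ingested minus fractional losses minus cost.

    balance = ingested - sda_loss*ingested - egestion_loss*ingested - cost;
    may be negative (an energetically unfavorable day).
    """
    c = c or EnergeticsConstants()
    ing = np.asarray(ingested, dtype=float)
    cost = np.asarray(movement_cost, dtype=float)
    out = ing * (1.0 - c.sda_loss - c.egestion_loss) - cost
    return float(out) if out.ndim == 0 else out


def length_to_weight(length, c: EnergeticsConstants | None = None):
    """Allometric length (cm) -> weight (kg): W = a * L^b."""
    c = c or EnergeticsConstants()
    L = np.asarray(length, dtype=float)
    if np.any(L <= 0):
        raise ValueError("length must be positive")
    out = c.lw_a * L ** c.lw_b
    return float(out) if out.ndim == 0 else out


def interpolate_length(release_date, release_length, recapture_date,
                       recapture_length, date):
    """Fork length on ``date`` assuming linear growth between release and
    recapture; endpoint dates return the recorded lengths exactly."""
    t0, t1 = pd.Timestamp(release_date), pd.Timestamp(recapture_date)
    t = pd.Timestamp(date)
    if not (t0 <= t <= t1):
        raise ValueError(f"date {t.date()} outside deployment [{t0.date()}, {t1.date()}]")
    span = (t1 - t0).total_seconds()
    if span == 0:
        return float(release_length)
    frac = (t - t0).total_seconds() / span
    return float(release_length + frac * (recapture_length - release_length))


# ---------------------------------------------------------------------------
# model fitting (thin wrappers over the additive-smooth engine)
# ---------------------------------------------------------------------------

DEPTH_PREDICTORS = ("t200", "moon_pct", "o2depth_3p5")


@dataclass
class ModelChain:
    """The five fitted objects of the framework (models 1a, 1b, 2, 3, 4)."""

    depth_day: SmoothModel
    depth_night: SmoothModel
    cost: SmoothModel
    hif: SmoothModel
    ingestion: SmoothModel

    def to_json_dir(self, directory) -> None:
        import os
        for name in ("depth_day", "depth_night", "cost", "hif", "ingestion"):
            getattr(self, name).to_json(os.path.join(os.fspath(directory), f"{name}.json"))

    @classmethod
    def from_json_dir(cls, directory) -> "ModelChain":
        import os
        return cls(**{
            name: SmoothModel.from_json(os.path.join(os.fspath(directory), f"{name}.json"))
            for name in ("depth_day", "depth_night", "cost", "hif", "ingestion")
        })


def fit_depth_models(day_data: pd.DataFrame, night_data: pd.DataFrame,
                     n_basis: int = 6) -> tuple[SmoothModel, SmoothModel]:
    """Models 1a/1b: day and night fish depth (m) from T200, moon-illumination
    percentage and the O2-3.5 depth.

    Each frame needs columns depth_m + DEPTH_PREDICTORS, one row per
    fish-day; rows with missing covariates are dropped (count logged by the
    engine's dropna).
    """
    terms = [SmoothTerm(p, n_basis=n_basis) for p in DEPTH_PREDICTORS]
    day = fit_gam(day_data, "depth_m", terms, units="m")
    night = fit_gam(night_data, "depth_m", terms, units="m")
    return day, night


def fit_cost_model(resp, n_basis: tuple[int, int] = (5, 5)) -> SmoothModel:
    """Model 2: metabolic movement cost over (temperature, swimming speed),
    fit as a tensor-product smooth.  Needs >= 50 rows spanning both axes."""
    df = resp.df if hasattr(resp, "df") else resp
    if len(df) < 50:
        raise ValueError("need >= 50 respirometry rows")
    for col in ("temperature_C", "speed_bls"):
        if np.ptp(np.asarray(df[col], dtype=float)) <= 1e-9:
            raise ValueError(f"respirometry data are one-dimensional ({col} constant)")
    term = TensorTerm(("temperature_C", "speed_bls"), n_basis=n_basis)
    return fit_gam(df, "mo2", [term], units="mg O2 kg-1 h-1")


def fit_hif_model(daily_hif_data: pd.DataFrame, n_basis: int = 6) -> SmoothModel:
    """Model 3: daily HIF (C*hour) from mesozooplankton biomass (mg C m-2),
    fish fork length (cm) and day length (h)."""
    terms = [SmoothTerm("mesozoo", n_basis=n_basis),
             SmoothTerm("length_cm", n_basis=n_basis),
             SmoothTerm("day_length_h", n_basis=n_basis)]
    return fit_gam(daily_hif_data, "hif", terms, units="C hour")


def fit_ingestion_model(trials, n_basis: int = 6) -> SmoothModel:
    """Model 4: kJ ingested from HIF, temperature and % finfish in the diet.
    Predictions are floored at zero at the point of use (a negative meal is
    a basis artifact, not biology)."""
    df = trials.df if hasattr(trials, "df") else trials
    terms = [SmoothTerm("hif", n_basis=n_basis),
             SmoothTerm("temperature_C", n_basis=n_basis),
             SmoothTerm("pct_finfish", n_basis=max(n_basis - 2, 4))]
    return fit_gam(df, "kj_ingested", terms, units="kJ")


def predict_ingested(model4: SmoothModel, hif, temperature, pct_finfish,
                     clamp: bool = True) -> np.ndarray:
    """Model-4 prediction floored at zero."""
    hif, temp, pct = np.broadcast_arrays(
        np.atleast_1d(np.asarray(hif, dtype=float)),
        np.asarray(temperature, dtype=float),
        np.asarray(pct_finfish, dtype=float))
    df = pd.DataFrame({"hif": hif, "temperature_C": temp, "pct_finfish": pct})
    return np.maximum(model4.predict(df, clamp=clamp), 0.0)
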