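"""Solar day length and lunar illumination.

Day length comes from the standard sunrise equation with the usual
low-precision solar declination; moon illuminated fraction from the synodic
phase (period 29.530588 days) anchored at the 2000-01-06 18:14 UTC new moon.
Both are adequate for the monthly/daily covariates the depth and foraging
models use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["day_length_hours", "moon_fraction"]

SYNODIC_DAYS = 29.530588
_NEW_MOON = pd.Timestamp("2000-01-06 18:14:00")


def _declination_deg(doy) -> np.ndarray:
    return 23.44 * np.sin(np.deg2rad(360.0 / 365.25 * (np.asarray(doy, dtype=float) + 284.0)))


def day_length_hours(lat, date) -> float | np.ndarray:
    """Astronomical day length (h) at latitude ``lat`` on ``date``.

    Polar night and polar day return 0 and 24 h rather than erroring.
    """
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("|lat| must be <= 90")
    doy = pd.DatetimeIndex(np.atleast_1d(np.asarray(date, dtype="datetime64[ns]"))).dayofyear.values
    decl = np.deg2rad(_declination_deg(doy))
    phi = np.deg2rad(lat)
    cos_h = -np.tan(phi) * np.tan(decl)
    cos_h = np.clip(cos_h, -1.0, 1.0)
    hours = 2.0 * np.rad2deg(np.arccos(cos_h)) / 15.0
    return float(hours[0]) if hours.size == 1 and np.ndim(lat) == 0 else hours


def moon_fraction(date) -> float | np.ndarray:
    """Moon illuminated fraction in percent (0 = new, 100 = full)."""
    d = pd.DatetimeIndex(np.atleast_1d(np.asarray(date, dtype="datetime64[ns]")))
    age = (d - _NEW_MOON).total_seconds().values / 86400.0
    phase = 2.0 * np.pi * (age % SYNODIC_DAYS) / SYNODIC_DAYS
    frac = 50.0 * (1.0 - np.cos(phase))
    return float(frac[0]) if frac.size == 1 and np.ndim(date) == 0 else frac
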