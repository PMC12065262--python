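"""Posterior-simulation uncertainty propagation through the model chain.

Each fitted model carries a Gaussian posterior approximation N(coef, cov).
Drawing k coefficient vectors per model and crossing the draws yields k^4
chain realizations per climate source (the two diel depth models share one
slot and are drawn jointly, so the product has exactly four factors).  The
defaults (k = 10, 5th/95th percentiles) give 10,000 realizations per source.

Spread attribution uses a one-factor-at-a-time design: the spread of a
scalar chain summary when only one slot varies (the others held at their
point estimates) measures that slot's contribution; the climate-source slot
enters through per-source summaries computed at the point estimates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from .energetics import ModelChain
from .gam import simulate_coefficients

__all__ = [
    "EnsembleSpec",
    "ChainEnsemble",
    "build_ensemble",
    "anomaly_percentiles",
    "variance_attribution",
    "slot_sweep",
]

SLOTS = ("depth", "cost", "hif", "ingestion")


@dataclass
class EnsembleSpec:
    """Posterior-ensemble settings: draws per model and reported percentiles."""

    k_per_model: int = 10
    seed: int = 0
    percentiles: tuple[float, ...] = (5.0, 95.0)
    slots: tuple[str, ...] = SLOTS

    def __post_init__(self) -> None:
        if self.k_per_model < 1:
            raise ValueError("k_per_model must be >= 1")
        ps = list(self.percentiles)
        if any(not (0 < p < 100) for p in ps) or ps != sorted(ps):
            raise ValueError("percentiles must be ascending and in (0, 100)")


@dataclass
class ChainEnsemble:
    """Lazy Cartesian product of per-slot posterior draws.

    ``draws[slot][i]`` is the i-th coefficient draw for that slot ("depth"
    holds a (day, night) pair).  Iterating yields (index_tuple, coefs_dict)
    pairs; the full set of chain predictions is never materialized here.
    """

    draws: dict = field(default_factory=dict)
    k: int = 1

    def __len__(self) -> int:
        return self.k ** len(SLOTS)

    def __iter__(self) -> Iterator[tuple[tuple[int, ...], dict]]:
        for idx in itertools.product(range(self.k), repeat=len(SLOTS)):
            yield idx, self.coefs_for(idx)

    def coefs_for(self, idx: tuple[int, ...]) -> dict:
        return {slot: self.draws[slot][i] for slot, i in zip(SLOTS, idx)}


def build_ensemble(models: ModelChain, spec: EnsembleSpec) -> ChainEnsemble:
    """Draw k coefficient vectors per slot from each model's posterior.

    The depth slot draws the day and night models jointly (one index selects
    a (day, night) coefficient pair), keeping the product four-way.  Raises
    if any model lacks a coefficient covariance.
    """
    for name in ("depth_day", "depth_night", "cost", "hif", "ingestion"):
        if getattr(models, name).cov is None:
            raise ValueError(f"model {name} carries no coefficient covariance")
    k = spec.k_per_model
    rng_seed = np.random.SeedSequence([spec.seed, 271828]).generate_state(5)
    day = simulate_coefficients(models.depth_day, k, seed=int(rng_seed[0]))
    night = simulate_coefficients(models.depth_night, k, seed=int(rng_seed[1]))
    draws = {
        "depth": [(day[i], night[i]) for i in range(k)],
        "cost": list(simulate_coefficients(models.cost, k, seed=int(rng_seed[2]))),
        "hif": list(simulate_coefficients(models.hif, k, seed=int(rng_seed[3]))),
        "ingestion": list(simulate_coefficients(models.ingestion, k, seed=int(rng_seed[4]))),
    }
    return ChainEnsemble(draws=draws, k=k)


def anomaly_percentiles(delta_maps, spec: EnsembleSpec) -> dict:
    """Per-cell empirical percentiles of ensemble balance-change maps.

    ``delta_maps`` is an iterable of equally-shaped arrays (one per ensemble
    member).  Returns ``{"p<q>": map}`` for each requested percentile plus
    ``"zero_overlap"``: True where the [first, last] percentile interval
    contains zero (the projected change is not distinguishable from none).
    """
    stack = np.stack([np.asarray(m, dtype=float) for m in delta_maps])
    if stack.shape[0] < 2:
        raise ValueError("need >= 2 ensemble members")
    out = {}
    for p in spec.percentiles:
        out[f"p{p:g}"] = np.percentile(stack, p, axis=0)
    lo = out[f"p{spec.percentiles[0]:g}"]
    hi = out[f"p{spec.percentiles[-1]:g}"]
    out["zero_overlap"] = (lo <= 0.0) & (hi >= 0.0)
    return out


def slot_sweep(models: ModelChain, spec: EnsembleSpec,
               evaluate: Callable[[dict | None], float]) -> dict[str, np.ndarray]:
    """One-factor-at-a-time sweep: for each slot, evaluate the chain summary
    with only that slot's k posterior draws substituted."""
    ens = build_ensemble(models, spec)
    out: dict[str, np.ndarray] = {}
    for slot in spec.slots:
        vals = [evaluate({slot: d}) for d in ens.draws[slot]]
        out[slot] = np.asarray(vals, dtype=float)
    return out


def variance_attribution(slot_summaries: dict[str, np.ndarray]) -> pd.DataFrame:
    """Rank spread contributions across slots (including a climate-source
    slot passed as per-source summaries).

    For each slot the spread is the variance of its summary values when only
    that slot varies.  Proportions are of the summed one-at-a-time variances
    — an attribution heuristic, not an exact decomposition, so interaction
    effects are not forced to zero.  Slots with fewer than two values are
    skipped.
    """
    rows = []
    for slot, vals in slot_summaries.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            continue
        rows.append({"slot": slot, "n": len(vals),
                     "variance": float(np.var(vals, ddof=1)),
                     "sd": float(np.std(vals, ddof=1))})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    total = df["variance"].sum()
    df["proportion"] = df["variance"] / total if total > 0 else 0.0
    return df.sort_values("variance", ascending=False).reset_index(drop=True)
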