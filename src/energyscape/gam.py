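"""Penalized additive smooth regression (a minimal Gaussian GAM).

All four biological models in the energetics framework are additive smooth
regressions: penalized cubic B-spline terms (optionally a tensor-product
interaction), smoothing parameters chosen by generalized cross-validation,
Gaussian/identity family throughout.  The fitted object keeps its coefficient
vector and Bayesian coefficient covariance so that downstream code can draw
from the approximate posterior and propagate uncertainty through the chained
framework.

Design matrix layout: an intercept column, then one centered basis block per
term.  Each smooth block carries a second-order difference penalty (P-spline);
the tensor block carries one difference penalty per margin.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize

logger = logging.getLogger("energyscape")

__all__ = [
    "SmoothTerm",
    "TensorTerm",
    "SmoothModel",
    "FitError",
    "fit_gam",
    "predict_gam",
    "simulate_coefficients",
]


class FitError(ValueError):
    """Raised when a model cannot be fit (rank deficiency, bad inputs)."""


@dataclass
class SmoothTerm:
    """One univariate term.

    basis="cubic" gives a penalized cubic B-spline with ``n_basis`` functions
    (knots at data quantiles); basis="linear" gives a single unpenalized
    centered linear column, useful as an exact least-squares reference.
    constraint is "none", "increasing" or "decreasing" and is enforced by
    post-fit projection of the partial response (monotone regression on a
    dense grid, coefficients re-solved against the projected curve).
    """

    name: str
    n_basis: int = 8
    basis: str = "cubic"
    constraint: str = "none"

    def __post_init__(self) -> None:
        if self.basis not in ("cubic", "linear"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.basis == "cubic" and self.n_basis < 4:
            raise ValueError("cubic terms need n_basis >= 4")
        if self.constraint not in ("none", "increasing", "decreasing"):
            raise ValueError(f"unknown constraint {self.constraint!r}")


@dataclass
class TensorTerm:
    """Tensor-product smooth of two predictors (row-wise Kronecker basis)."""

    names: tuple[str, str]
    n_basis: tuple[int, int] = (5, 5)

    @property
    def name(self) -> str:
        return f"te({self.names[0]},{self.names[1]})"


def _quantile_knots(x: np.ndarray, n_basis: int) -> np.ndarray:
    """Clamped cubic knot vector with interior knots at data quantiles."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise FitError(f"predictor has zero range (min == max == {lo})")
    n_interior = n_basis - 4
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        # knots must be strictly inside and non-decreasing; nudge duplicates
        interior = np.clip(interior, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
        interior = np.maximum.accumulate(interior)
    else:
        interior = np.array([])
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def _bspline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Cubic B-spline design matrix, linearly extrapolated outside the knots.

    Clamped prediction (the chained-framework default) never leaves the knot
    range; unclamped prediction extends each basis function linearly from the
    boundary, which keeps values finite and differentiable.
    """
    lo, hi = knots[0], knots[-1]
    xc = np.clip(x, lo, hi)
    B = BSpline.design_matrix(xc, knots, 3).toarray()
    below, above = x < lo, x > hi
    if below.any() or above.any():
        eps = 1e-6 * (hi - lo)
        for mask, edge, sgn in ((below, lo, 1.0), (above, hi, -1.0)):
            if mask.any():
                B0 = BSpline.design_matrix(np.array([edge]), knots, 3).toarray()[0]
                B1 = BSpline.design_matrix(np.array([edge + sgn * eps]), knots, 3).toarray()[0]
                slope = (B1 - B0) / (sgn * eps)
                B[mask] = B0 + np.outer(x[mask] - edge, slope)
    return B


def _diff_penalty(q: int, order: int = 2) -> np.ndarray:
    if q <= order:
        return np.zeros((q, q))
    D = np.diff(np.eye(q), n=order, axis=0)
    return D.T @ D


@dataclass
class _TermState:
    """Frozen basis description for one fitted block (serializable).

    ``Z`` is the sum-to-zero reparameterization: the raw spline basis spans
    the constant function (partition of unity), which would alias the
    intercept, so each block is projected onto the null space of its training
    column-sum vector.  Coefficients live in the reduced (q-1 dimensional)
    space.
    """

    kind: str                      # "cubic" | "linear" | "tensor"
    names: list[str]
    knots: list[np.ndarray]        # one knot vector per margin ("linear": data mean)
    Z: np.ndarray                  # (q_raw, n_coef) reparameterization
    n_coef: int
    constraint: str = "none"
    constraint_applied: bool = False

    def raw_design(self, data: pd.DataFrame) -> np.ndarray:
        cols = []
        for nm in self.names:
            if nm not in data:
                raise KeyError(f"missing predictor column {nm!r}")
            cols.append(np.asarray(data[nm], dtype=float))
        if self.kind == "linear":
            return (cols[0] - self.knots[0][0])[:, None]
        if self.kind == "cubic":
            return _bspline_design(cols[0], self.knots[0])
        B1 = _bspline_design(cols[0], self.knots[0])
        B2 = _bspline_design(cols[1], self.knots[1])
        return np.einsum("ij,ik->ijk", B1, B2).reshape(len(B1), -1)

    def design(self, data: pd.DataFrame) -> np.ndarray:
        return self.raw_design(data) @ self.Z

    def penalties(self) -> list[np.ndarray]:
        if self.kind == "linear":
            return []
        if self.kind == "cubic":
            q = len(self.knots[0]) - 4
            return [self.Z.T @ _diff_penalty(q) @ self.Z]
        q1 = len(self.knots[0]) - 4
        q2 = len(self.knots[1]) - 4
        return [
            self.Z.T @ np.kron(_diff_penalty(q1), np.eye(q2)) @ self.Z,
            self.Z.T @ np.kron(np.eye(q1), _diff_penalty(q2)) @ self.Z,
        ]


@dataclass
class SmoothModel:
    """A fitted additive smooth regression.

    Holds everything needed to predict, to report percent deviance explained,
    and to simulate coefficient vectors from the Gaussian posterior
    approximation N(coef, cov).
    """

    response: str
    units: str
    term_states: list[_TermState]
    coef: np.ndarray
    cov: np.ndarray
    lambdas: np.ndarray
    ranges: dict[str, tuple[float, float]]
    sigma2: float
    deviance_explained: float      # percent, in [0, 100]
    n_obs: int
    edf: float
    meta: dict = field(default_factory=dict)

    # -- prediction ------------------------------------------------------
    def design(self, data: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        data = self._clamped(data) if clamp else data
        n = len(data)
        blocks = [np.ones((n, 1))]
        blocks += [ts.design(data) for ts in self.term_states]
        return np.hstack(blocks)

    def _clamped(self, data: pd.DataFrame) -> pd.DataFrame:
        out = data.copy()
        n_clamped = 0
        for name, (lo, hi) in self.ranges.items():
            x = np.asarray(out[name], dtype=float)
            bad = (x < lo) | (x > hi)
            n_clamped += int(bad.sum())
            if bad.any():
                out[name] = np.clip(x, lo, hi)
        if n_clamped:
            logger.debug(
                "%s: clamped %d predictor values to training range", self.response, n_clamped
            )
            self.meta["clamped_total"] = self.meta.get("clamped_total", 0) + n_clamped
        return out

    def predict(self, data: pd.DataFrame, clamp: bool = True,
                coef: np.ndarray | None = None) -> np.ndarray:
        """Predicted response; ``coef`` substitutes a simulated draw."""
        beta = self.coef if coef is None else np.asarray(coef)
        return self.design(data, clamp=clamp) @ beta

    def partial_response(self, term_name: str, grid: np.ndarray,
                         coef: np.ndarray | None = None) -> np.ndarray:
        """Centered contribution of one univariate term on a grid."""
        beta = self.coef if coef is None else np.asarray(coef)
        idx = 1
        for ts in self.term_states:
            if ts.names == [term_name]:
                df = pd.DataFrame({term_name: grid})
                return ts.design(df) @ beta[idx:idx + ts.n_coef]
            idx += ts.n_coef
        raise KeyError(f"no univariate term {term_name!r}")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "units": self.units,
            "terms": [
                {
                    "kind": ts.kind,
                    "names": ts.names,
                    "knots": [k.tolist() for k in ts.knots],
                    "Z": ts.Z.tolist(),
                    "n_coef": ts.n_coef,
                    "constraint": ts.constraint,
                    "constraint_applied": ts.constraint_applied,
                }
                for ts in self.term_states
            ],
            "coef": self.coef.tolist(),
            "cov": self.cov.tolist(),
            "lambdas": self.lambdas.tolist(),
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "sigma2": self.sigma2,
            "deviance_explained": self.deviance_explained,
            "n_obs": self.n_obs,
            "edf": self.edf,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SmoothModel":
        states = [
            _TermState(
                kind=t["kind"],
                names=list(t["names"]),
                knots=[np.asarray(k) for k in t["knots"]],
                Z=np.asarray(t["Z"]),
                n_coef=t["n_coef"],
                constraint=t.get("constraint", "none"),
                constraint_applied=t.get("constraint_applied", False),
            )
            for t in d["terms"]
        ]
        return cls(
            response=d["response"],
            units=d["units"],
            term_states=states,
            coef=np.asarray(d["coef"]),
            cov=np.asarray(d["cov"]),
            lambdas=np.asarray(d["lambdas"]),
            ranges={k: (v[0], v[1]) for k, v in d["ranges"].items()},
            sigma2=d["sigma2"],
            deviance_explained=d["deviance_explained"],
            n_obs=d["n_obs"],
            edf=d["edf"],
            meta=d.get("meta", {}),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "SmoothModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _sum_to_zero_Z(B: np.ndarray) -> np.ndarray:
    """Null-space basis of the column-sum constraint 1'B beta = 0."""
    c = B.sum(axis=0)
    nrm = np.linalg.norm(c)
    if nrm == 0:
        return np.eye(B.shape[1])
    Q, _ = np.linalg.qr(np.column_stack([c / nrm, np.eye(B.shape[1])[:, :-1]]))
    # first column of Q spans c; remaining columns span its null space
    return Q[:, 1:]


def _build_states(data: pd.DataFrame, terms) -> list[_TermState]:
    states = []
    for t in terms:
        if isinstance(t, TensorTerm):
            knots = []
            for nm, q in zip(t.names, t.n_basis):
                x = np.asarray(data[nm], dtype=float)
                try:
                    knots.append(_quantile_knots(x, q))
                except FitError as e:
                    raise FitError(f"term {t.name}: {e}") from None
            q_raw = t.n_basis[0] * t.n_basis[1]
            st = _TermState("tensor", list(t.names), knots, np.eye(q_raw), q_raw)
        elif t.basis == "linear":
            x = np.asarray(data[t.name], dtype=float)
            st = _TermState("linear", [t.name], [np.array([float(np.mean(x))])],
                            np.eye(1), 1, constraint=t.constraint)
        else:
            x = np.asarray(data[t.name], dtype=float)
            try:
                knots = _quantile_knots(x, t.n_basis)
            except FitError as e:
                raise FitError(f"term {t.name}: {e}") from None
            st = _TermState("cubic", [t.name], [knots], np.eye(t.n_basis),
                            t.n_basis, constraint=t.constraint)
        if st.kind in ("cubic", "tensor"):
            st.Z = _sum_to_zero_Z(st.raw_design(data))
            st.n_coef = st.Z.shape[1]
        states.append(st)
    return states


def _penalty_matrix(states: list[_TermState], lambdas: np.ndarray, p: int) -> np.ndarray:
    S = np.zeros((p, p))
    idx, li = 1, 0
    for ts in states:
        for P in ts.penalties():
            S[idx:idx + ts.n_coef, idx:idx + ts.n_coef] += lambdas[li] * P
            li += 1
        idx += ts.n_coef
    return S


def _solve(XtX, Xty, S):
    A = XtX + S
    try:
        return np.linalg.solve(A, Xty), A
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, Xty, rcond=None)[0], A


def fit_gam(
    data: pd.DataFrame,
    response: str,
    terms,
    family: str = "gaussian",
    method: str = "gcv",
    lam: np.ndarray | None = None,
    units: str = "",
) -> SmoothModel:
    """Fit a penalized additive smooth regression.

    Parameters
    ----------
    data : training frame containing the response and every predictor.
    response : response column name.
    terms : sequence of SmoothTerm / TensorTerm.
    method : "gcv" (smoothing parameters minimize generalized
        cross-validation on a log scale) or "fixed" (use ``lam``).
    lam : fixed smoothing parameters, one per penalty, for method="fixed".

    Raises
    ------
    FitError : fewer than 10 rows per term, missing values, a predictor with
        zero range, or a rank-deficient block (named in the message).
    """
    if family != "gaussian":
        raise ValueError("only the gaussian/identity family is supported")
    terms = list(terms)
    names = {n for t in terms for n in ([t.name] if isinstance(t, SmoothTerm) else list(t.names))}
    cols = sorted(names) + [response]
    for c in cols:
        if c not in data:
            raise FitError(f"column {c!r} not in data")
    df = data[cols].dropna()
    if len(df) < 10 * len(terms):
        raise FitError(f"need >= {10 * len(terms)} complete rows, got {len(df)}")

    y = np.asarray(df[response], dtype=float)
    n = len(y)
    states = _build_states(df, terms)
    blocks = [ts.design(df) for ts in states]
    for ts, B in zip(states, blocks):
        if np.linalg.matrix_rank(B) < min(B.shape):
            raise FitError(f"rank-deficient design for term {'*'.join(ts.names)}")
    X = np.hstack([np.ones((n, 1))] + blocks)
    p = X.shape[1]
    XtX, Xty = X.T @ X, X.T @ y
    n_pen = sum(len(ts.penalties()) for ts in states)

    def fit_at(loglam: np.ndarray):
        loglam = np.clip(np.asarray(loglam, dtype=float), -8.0, 8.0)
        S = _penalty_matrix(states, 10.0 ** loglam, p)
        beta, A = _solve(XtX, Xty, S)
        Ainv = np.linalg.pinv(A)
        edf = float(np.trace(Ainv @ XtX))
        rss = float(np.sum((y - X @ beta) ** 2))
        return beta, Ainv, edf, rss

    if n_pen == 0:
        loglam = np.array([])
    elif method == "fixed":
        if lam is None or len(np.atleast_1d(lam)) != n_pen:
            raise ValueError(f"method='fixed' needs {n_pen} smoothing parameters")
        loglam = np.log10(np.atleast_1d(lam).astype(float))
    elif method == "gcv":
        def gcv(ll):
            _, _, edf, rss = fit_at(ll)
            denom = max(n - edf, 1e-6)
            out = n * rss / denom ** 2
            return out if np.isfinite(out) else 1e300

        x0 = np.zeros(n_pen)
        res = minimize(gcv, x0, method="Nelder-Mead",
                       options={"xatol": 0.05, "fatol": 1e-10, "maxiter": 200 * n_pen})
        loglam = np.clip(res.x, -8, 8)
    else:
        raise ValueError(f"unknown smoothing method {method!r}")

    beta, Ainv, edf, rss = fit_at(loglam)
    sigma2 = rss / max(n - edf, 1.0)
    cov = sigma2 * Ainv
    cov = (cov + cov.T) / 2.0

    tss = float(np.sum((y - y.mean()) ** 2))
    dev = 0.0 if tss <= 1e-300 else 100.0 * max(0.0, 1.0 - rss / tss)

    ranges = {nm: (float(df[nm].min()), float(df[nm].max())) for nm in sorted(names)}
    model = SmoothModel(
        response=response, units=units, term_states=states,
        coef=beta, cov=cov, lambdas=10.0 ** loglam, ranges=ranges,
        sigma2=sigma2, deviance_explained=min(dev, 100.0), n_obs=n, edf=edf,
    )
    _apply_constraints(model, df)
    return model


def _apply_constraints(model: SmoothModel, df: pd.DataFrame) -> None:
    """Project constrained partial responses onto monotone curves.

    Monotone regression (PAVA) of the fitted partial response on a dense
    grid, then a ridge-stabilized least-squares re-solve of that term's
    coefficients against the projected curve.  The coefficient covariance is
    kept from the unconstrained fit (documented approximation).
    """
    from sklearn.isotonic import IsotonicRegression

    idx = 1
    for ts in model.term_states:
        if ts.kind != "cubic" or ts.constraint == "none":
            idx += ts.n_coef
            continue
        lo, hi = model.ranges[ts.names[0]]
        grid = np.linspace(lo, hi, 200)
        Bg = ts.design(pd.DataFrame({ts.names[0]: grid}))
        f = Bg @ model.coef[idx:idx + ts.n_coef]
        increasing = ts.constraint == "increasing"
        diffs = np.diff(f)
        ok = np.all(diffs >= -1e-9) if increasing else np.all(diffs <= 1e-9)
        if not ok:
            iso = IsotonicRegression(increasing=increasing).fit(grid, f)
            target = iso.predict(grid)
            ridge = 1e-8 * np.eye(ts.n_coef)
            beta_t = np.linalg.solve(Bg.T @ Bg + ridge, Bg.T @ target)
            model.coef[idx:idx + ts.n_coef] = beta_t
            ts.constraint_applied = True
            logger.warning("monotone projection applied to term %s", ts.names[0])
        idx += ts.n_coef


# ---------------------------------------------------------------------------
# functional front-ends
# ---------------------------------------------------------------------------

def predict_gam(model: SmoothModel, newdata: pd.DataFrame, clamp: bool = True,
                coef: np.ndarray | None = None) -> np.ndarray:
    """Evaluate a fitted model on new data (see SmoothModel.predict)."""
    return model.predict(newdata, clamp=clamp, coef=coef)


def simulate_coefficients(model: SmoothModel, k: int, seed: int | None = None) -> np.ndarray:
    """Draw ``k`` coefficient vectors from N(coef, cov).

    A covariance with (numerically) negative eigenvalues is repaired by
    flooring them at zero before factorization; the repair is logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if model.cov is None:
        raise ValueError("model carries no coefficient covariance")
    rng = np.random.default_rng(seed)
    w, V = np.linalg.eigh(model.cov)
    if np.any(w < 0):
        if np.any(w < -1e-8 * max(1.0, w.max())):
            logger.warning("covariance repaired: floored %d negative eigenvalues",
                           int((w < 0).sum()))
        w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)
    z = rng.standard_normal((k, len(model.coef)))
    return model.coef + z @ L.T
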