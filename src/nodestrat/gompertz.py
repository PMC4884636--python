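"""Inverse Gompertzian relative-survival kinetics and inflection points.

The model is

    RS(t) = 1 - b1 * exp(-b2 * exp(-b3 * t)),        t in years,

a sigmoid that declines slowly early on and then drops exponentially; its
derivative

    dRS/dt = -b1 * b2 * b3 * exp(-b2 * exp(-b3 * t)) * exp(-b3 * t)

is most negative at the inflection point (IP) t = ln(b2)/b3 (for b2 > 1;
for b2 <= 1 the derivative is most negative at t = 0). The IP marks the
transition from the slow early decline — the window in which treatment can
still be regarded as successful — to the late exponential decline, and
depends only on b2 and b3.

Fitting is plain least squares on the monthly relative-survival grid
(t = month/12), in two stages: a seeded differential-evolution global
search followed by deterministic Nelder-Mead refinement. b1 is allowed to
exceed 1 (the fit is unconstrained model evaluation, not a survival law),
in which case the large-t limit 1 - b1 is negative; a flag records when a
parameter sits at a bound.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import differential_evolution, minimize, minimize_scalar

from .errors import InsufficientDataError

try:  # sklearn is optional at runtime; the estimator degrades gracefully
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        def get_params(self, deep=True):
            return dict(self.__dict__)

        def set_params(self, **params):
            for k, v in params.items():
                setattr(self, k, v)
            return self


DEFAULT_BOUNDS = ((1e-8, 5.0), (1e-8, 50.0), (1e-8, 2.0))


def _check_params(b1, b2, b3) -> None:
    if b1 <= 0 or b2 <= 0 or b3 <= 0:
        raise ValueError(f"parameters must be positive, got {(b1, b2, b3)}")


def inverse_gompertz_rs(t, b1: float, b2: float, b3: float):
    """Model relative survival at time ``t`` (years). Vectorized in ``t``.

    Values may leave [0, 1] for b1 > 1 at large t; evaluation is
    deliberately unconstrained.
    """
    _check_params(b1, b2, b3)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = 1.0 - b1 * np.exp(-b2 * np.exp(-b3 * t))
    return float(out) if out.ndim == 0 else out


def rs_derivative(t, b1: float, b2: float, b3: float):
    """Closed-form dRS/dt (per year); always <= 0. Vectorized in ``t``."""
    _check_params(b1, b2, b3)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    e = np.exp(-b3 * t)
    out = -b1 * b2 * b3 * np.exp(-b2 * e) * e
    return float(out) if out.ndim == 0 else out


def inflection_point(b2: float, b3: float, search_init: float | None = None) -> float:
    """Time (years) at which the model derivative is most negative.

    Found by numerical minimization of ``rs_derivative`` over t >= 0 (b1
    scales out of the argmin and is fixed at 1). For b2 > 1 this agrees
    with the closed form ln(b2)/b3; for b2 <= 1 the minimum sits on the
    boundary t = 0, which is returned with a warning.
    """
    _check_params(1.0, b2, b3)
    if b2 <= 1.0:
        warnings.warn(
            "b2 <= 1: derivative is most negative at t = 0 (boundary)",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    init = search_init if search_init is not None else np.log(b2) / b3
    hi = max(4.0 * init, 10.0 / b3, 1.0)
    res = minimize_scalar(
        lambda t: rs_derivative(t, 1.0, b2, b3),
        bounds=(0.0, hi),
        method="bounded",
        options={"xatol": 1e-10, "maxiter": 2000},
    )
    x = float(res.x)
    # one guarded Newton step on the stationarity condition sharpens the
    # bounded search to well below 1e-6 years even for IPs of ~500 years
    for _ in range(3):
        e = math.exp(-b3 * x)
        # d/dt log|dRS/dt| = b2*b3*e - b3; root at e = 1/b2
        g = b2 * b3 * e - b3
        gp = -b3 * b2 * b3 * e
        if gp == 0.0:
            break
        step = g / gp
        if not math.isfinite(step):
            break
        x = max(0.0, x - step)
    return x


@dataclass
class GompertzFit:
    """Result of a least-squares inverse Gompertz fit to one RS curve."""

    b1: float
    b2: float
    b3: float
    sse: float
    r_squared: float
    ip_years: float
    optimizer_seed: int
    converged: bool
    at_bound: bool
    sse_global: float  # objective after the global stage, before refinement
    n_points: int

    def to_dict(self) -> dict:
        return asdict(self)


class InverseGompertzRS(BaseEstimator):
    """Least-squares inverse Gompertz fit, scikit-learn style.

    Parameters
    ----------
    bounds : three (low, high) pairs for (b1, b2, b3). Defaults admit
        b1 up to 5 so fits may exceed a proper survival law, matching how
        registry RS curves with very flat tails are usually summarized.
    seed : int, seeds the global (evolutionary) search stage.
    maxiter, popsize : differential-evolution budget.

    Attributes (after ``fit``)
    --------------------------
    b1_, b2_, b3_ : fitted parameters (b3_ per year).
    sse_, r_squared_ : goodness of fit on the training grid.
    ip_years_ : inflection point ln(b2)/b3 found numerically.
    converged_, at_bound_ : optimizer diagnostics.
    """

    def __init__(
        self,
        bounds=DEFAULT_BOUNDS,
        seed: int = 0,
        maxiter: int = 300,
        popsize: int = 25,
    ):
        self.bounds = bounds
        self.seed = seed
        self.maxiter = maxiter
        self.popsize = popsize

    def fit(self, t: Sequence[float], rs: Sequence[float]) -> "InverseGompertzRS":
        """Fit to curve values ``rs`` observed at times ``t`` (years)."""
        t = np.asarray(t, dtype=float)
        rs = np.asarray(rs, dtype=float)
        if t.ndim != 1 or t.shape != rs.shape:
            raise ValueError("t and rs must be 1-D arrays of equal length")
        if len(t) < 4:
            raise InsufficientDataError(
                f"need at least 4 curve points to fit 3 parameters, got {len(t)}"
            )
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(rs)):
            raise ValueError("t and rs must be finite")
        bounds = [(float(lo), float(hi)) for lo, hi in self.bounds]

        def objective(params):
            b1, b2, b3 = params
            resid = 1.0 - b1 * np.exp(-b2 * np.exp(-b3 * t)) - rs
            return float(resid @ resid)

        glob = differential_evolution(
            objective,
            bounds,
            seed=int(self.seed),
            maxiter=int(self.maxiter),
            popsize=int(self.popsize),
            tol=1e-12,
            polish=False,
            init="latinhypercube",
        )
        self.sse_global_ = float(glob.fun)
        loc = minimize(
            objective,
            glob.x,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
        )
        # Refinement is unconstrained; keep it only if feasible and better.
        x, fun = glob.x, float(glob.fun)
        in_bounds = all(lo <= v <= hi for v, (lo, hi) in zip(loc.x, bounds))
        if in_bounds and float(loc.fun) <= fun:
            x, fun = loc.x, float(loc.fun)
        self.b1_, self.b2_, self.b3_ = (float(v) for v in x)
        self.sse_ = fun
        ss_tot = float(np.sum((rs - rs.mean()) ** 2))
        self.r_squared_ = 1.0 - fun / ss_tot if ss_tot > 0 else float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.ip_years_ = (
                inflection_point(self.b2_, self.b3_) if self.b2_ > 1.0 else 0.0
            )
        self.converged_ = bool(glob.success or loc.success)
        rel = 1e-6
        self.at_bound_ = any(
            v - lo <= rel * (hi - lo) or hi - v <= rel * (hi - lo)
            for v, (lo, hi) in zip(x, bounds)
        )
        if self.at_bound_:
            warnings.warn(
                "optimizer solution lies on a parameter bound", RuntimeWarning
            )
        if self.b1_ > 1.0:
            warnings.warn(
                "fitted b1 > 1: curve is not a proper survival law as t -> inf",
                RuntimeWarning,
            )
        self.n_points_ = int(len(t))
        return self

    def predict(self, t: Sequence[float]) -> np.ndarray:
        """Model relative survival at times ``t`` (years)."""
        if not hasattr(self, "b1_"):
            raise AttributeError("estimator is not fitted yet; call fit() first")
        return np.asarray(
            inverse_gompertz_rs(np.asarray(t, dtype=float), self.b1_, self.b2_, self.b3_)
        )


def fit_inverse_gompertz(
    curve,
    bounds=DEFAULT_BOUNDS,
    seed: int = 0,
    truncate_month: int | None = None,
) -> GompertzFit:
    """Fit the model to a :class:`RelativeSurvivalCurve` (monthly grid).

    ``truncate_month`` optionally limits the fit to the first part of the
    curve; by default the whole supplied grid is used, with months
    converted to years (t = m/12).
    """
    grid = np.asarray(curve.time_grid, dtype=float)
    rs = np.asarray(curve.rs, dtype=float)
    if truncate_month is not None:
        keep = grid <= truncate_month
        grid, rs = grid[keep], rs[keep]
    est = InverseGompertzRS(bounds=bounds, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est.fit(grid / 12.0, rs)
    return GompertzFit(
        b1=est.b1_,
        b2=est.b2_,
        b3=est.b3_,
        sse=est.sse_,
        r_squared=est.r_squared_,
        ip_years=est.ip_years_,
        optimizer_seed=int(seed),
        converged=est.converged_,
        at_bound=est.at_bound_,
        sse_global=est.sse_global_,
        n_points=est.n_points_,
    )
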