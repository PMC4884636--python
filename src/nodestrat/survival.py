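"""Observed, expected and relative survival on a monthly grid.

Observed survival is the Kaplan–Meier product-limit estimator with
Greenwood standard errors. Relative survival divides observed by Ederer II
expected survival and then applies two registry correction rules, in order:
values exceeding 100% are capped at 1.0, and any remaining increase is
replaced by the value of the previous period (a left-to-right carry-back
pass), so the reported relative-survival curve is non-increasing by
construction.

Tied deaths and censorings at the same month follow the standard KM
convention: deaths are processed first, so subjects censored at month m
still count as at risk for deaths at month m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateTestError,
    GridAlignmentError,
    UndefinedRatioError,
)
from .life_tables import ExpectedSurvivalCurve
from .records import PatientRecord, event_arrays

CORRECTION_NONE = "none"
CORRECTION_CAPPED = "capped"
CORRECTION_CARRIED = "carried_back"


@dataclass
class SurvivalCurve:
    """Kaplan–Meier observed survival on months 0..M."""

    time_grid: np.ndarray
    survival: np.ndarray
    std_err: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        self.time_grid = np.asarray(self.time_grid, dtype=np.int64)
        self.survival = np.asarray(self.survival, dtype=float)
        self.std_err = np.asarray(self.std_err, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.time_grid)

    def _index(self, month: int) -> int:
        hits = np.flatnonzero(self.time_grid == month)
        if len(hits) == 0:
            raise GridAlignmentError(f"month {month} not on curve grid")
        return int(hits[0])

    def at(self, month: int) -> float:
        return float(self.survival[self._index(month)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": self.time_grid,
                "survival": self.survival,
                "std_err": self.std_err,
                "n_at_risk": self.n_at_risk,
            }
        )


@dataclass
class RelativeSurvivalCurve:
    """Relative survival after capping and monotone correction."""

    time_grid: np.ndarray
    rs: np.ndarray
    std_err: np.ndarray
    corrections_applied: np.ndarray  # per-month: none / capped / carried_back

    def __post_init__(self):
        self.time_grid = np.asarray(self.time_grid, dtype=np.int64)
        self.rs = np.asarray(self.rs, dtype=float)
        self.std_err = np.asarray(self.std_err, dtype=float)
        self.corrections_applied = np.asarray(self.corrections_applied, dtype=object)

    def __len__(self) -> int:
        return len(self.time_grid)

    def _index(self, month: int) -> int:
        hits = np.flatnonzero(self.time_grid == month)
        if len(hits) == 0:
            raise GridAlignmentError(f"month {month} not on curve grid")
        return int(hits[0])

    def at(self, month: int) -> float:
        return float(self.rs[self._index(month)])

    def se_at(self, month: int) -> float:
        return float(self.std_err[self._index(month)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": self.time_grid,
                "relative_survival": self.rs,
                "std_err": self.std_err,
                "correction_flag": self.corrections_applied,
            }
        )


@dataclass
class ZTestResult:
    month: int
    rs_a: float
    rs_b: float
    z: float
    p: float


@dataclass
class LogRankResult:
    statistic: float  # chi-square, 1 df
    p: float


def km_estimate(cohort: Sequence[PatientRecord], max_months: int) -> SurvivalCurve:
    """Kaplan–Meier observed survival on the monthly grid 0..max_months.

    Deaths at month m reduce survival at m; censored subjects leave the risk
    set after month m. The Greenwood variance S(t)^2 * sum d_j/(n_j(n_j-d_j))
    accumulates over event months. Events recorded with zero months of
    follow-up are counted in the first interval so that S(0) = 1.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if max_months < 1:
        raise ValueError("max_months must be >= 1")
    t, d = event_arrays(cohort)
    t = np.maximum(t, 1)  # month-0 events counted in month 1

    months = np.arange(max_months + 1)
    # n_at_risk[m]: subjects with follow-up >= m (alive and uncensored just
    # before month m); events beyond the grid keep subjects at risk throughout.
    n_at_risk = np.array([(t >= m).sum() for m in months], dtype=np.int64)
    deaths = np.bincount(t[d & (t <= max_months)], minlength=max_months + 1)

    surv = np.ones(max_months + 1)
    gw = np.zeros(max_months + 1)  # running Greenwood sum
    s, g = 1.0, 0.0
    for m in range(1, max_months + 1):
        n_m, d_m = int(n_at_risk[m]), int(deaths[m])
        if d_m > 0:
            s *= 1.0 - d_m / n_m
            if n_m > d_m:
                g += d_m / (n_m * (n_m - d_m))
        surv[m] = s
        gw[m] = g
    se = surv * np.sqrt(gw)
    se[surv == 0.0] = 0.0
    return SurvivalCurve(months, surv, se, n_at_risk)


def relative_survival(
    observed: SurvivalCurve, expected: ExpectedSurvivalCurve
) -> RelativeSurvivalCurve:
    """Observed/expected ratio with capping at 100% then monotone carry-back.

    The two grids must share the monthly spacing from 0; if one is a
    truncation of the other, the result is computed on the common prefix.
    The standard error is the observed Greenwood SE divided by expected
    survival (expected survival treated as deterministic).
    """
    m = min(len(observed), len(expected))
    if not np.array_equal(observed.time_grid[:m], expected.time_grid[:m]):
        raise GridAlignmentError(
            "observed and expected curves are on different time grids"
        )
    obs = observed.survival[:m]
    exp = expected.values[:m]
    if np.any((exp == 0.0) & (obs > 0.0)):
        bad = int(np.argmax((exp == 0.0) & (obs > 0.0)))
        raise UndefinedRatioError(
            f"expected survival is 0 at month {bad} while observed survival "
            f"is {obs[bad]:.4g}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(exp > 0.0, obs / exp, 0.0)
        se = np.where(exp > 0.0, observed.std_err[:m] / exp, 0.0)

    flags = np.array([CORRECTION_NONE] * m, dtype=object)
    rs = raw.copy()
    capped = rs > 1.0
    rs[capped] = 1.0
    flags[capped] = CORRECTION_CAPPED
    for j in range(1, m):
        if rs[j] > rs[j - 1]:
            rs[j] = rs[j - 1]
            flags[j] = CORRECTION_CARRIED
    return RelativeSurvivalCurve(observed.time_grid[:m], rs, se, flags)


def rs_z_test(
    curve_a: RelativeSurvivalCurve,
    curve_b: RelativeSurvivalCurve,
    at_month: int,
) -> ZTestResult:
    """Two-sided Z-test for a difference in relative survival at one month,
    treating the two curves as independent."""
    ra, rb = curve_a.at(at_month), curve_b.at(at_month)
    sa, sb = curve_a.se_at(at_month), curve_b.se_at(at_month)
    if sa == 0.0 and sb == 0.0:
        if ra == rb:
            return ZTestResult(at_month, ra, rb, 0.0, 1.0)
        raise DegenerateTestError(
            "both standard errors are zero but the values differ"
        )
    z = (ra - rb) / float(np.hypot(sa, sb))
    p = 2.0 * stats.norm.sf(abs(z))
    return ZTestResult(at_month, ra, rb, float(z), float(p))


def logrank_test(
    cohort_a: Sequence[PatientRecord], cohort_b: Sequence[PatientRecord]
) -> LogRankResult:
    """Two-group two-tailed log-rank test on observed survival."""
    if not cohort_a or not cohort_b:
        raise ValueError("both cohorts must be non-empty")
    ta, da = event_arrays(cohort_a)
    tb, db = event_arrays(cohort_b)
    if not (da.any() or db.any()):
        raise DegenerateTestError("no deaths in either group; log-rank undefined")
    from lifelines.statistics import logrank_test as _ll_logrank

    res = _ll_logrank(ta, tb, event_observed_A=da, event_observed_B=db)
    return LogRankResult(float(res.test_statistic), float(res.p_value))
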