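"""Percent nodal involvement (%LN+) stratification and the cutoff scan.

%LN+ is the ratio of pathologically positive lymph nodes to nodes examined
at surgery. The cutoff scan fits an inverse Gompertz relative-survival
model to the sub-cohort of patients with %LN+ below each cutoff in a
grid and tabulates the resulting inflection points; the three-group
stratification splits the LN+ cohort at the chosen boundaries (default
10% and 40%, the top group closed so that %LN+ = 40% belongs to the
">=40%" group) and runs the full relative-survival pipeline per group,
with pairwise Z-tests at fixed months and pairwise log-rank tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, DegenerateTestError
from .gompertz import GompertzFit, fit_inverse_gompertz
from .life_tables import LifeTable, ederer2_expected
from .records import PatientRecord
from .survival import (
    RelativeSurvivalCurve,
    SurvivalCurve,
    ZTestResult,
    km_estimate,
    logrank_test,
    relative_survival,
    rs_z_test,
)

#: Below this sub-cohort size a three-parameter fit is too unstable to report.
MIN_GROUP_SIZE = 50

#: Default cutoff grid for the scan: 5% to 100% in 2.5% steps.
DEFAULT_CUTOFFS = tuple(np.round(np.arange(0.05, 1.0 + 1e-9, 0.025), 4))

DEFAULT_BOUNDARIES = (0.10, 0.40)
DEFAULT_TEST_MONTHS = (60, 120, 180)


def percent_ln_positive(record: PatientRecord) -> float:
    """nodes_positive / nodes_examined; NaN signals an excluded record
    (no nodes examined)."""
    if record.nodes_examined == 0:
        return float("nan")
    if record.nodes_positive > record.nodes_examined:
        raise DataIntegrityError(
            f"nodes_positive > nodes_examined for {record.patient_id!r}"
        )
    return record.nodes_positive / record.nodes_examined


def filter_cohort(
    cohort: Sequence[PatientRecord],
    ln_positive_required: bool = False,
    race: str | None = None,
    grade: str | None = None,
    radiation: str | None = None,
) -> list[PatientRecord]:
    """Sub-cohort matching all supplied criteria.

    Records with the value ``"unknown"`` in a filtered field are excluded
    (an unknown grade cannot be shown to be grade III).
    """
    out = []
    for r in cohort:
        if ln_positive_required and r.nodes_positive < 1:
            continue
        if race is not None and r.race != race:
            continue
        if grade is not None and r.grade != grade:
            continue
        if radiation is not None and r.radiation != radiation:
            continue
        out.append(r)
    if not out:
        warnings.warn("filter criteria exclude every record", UserWarning)
    return out


def _ln_positive_cohort(cohort: Sequence[PatientRecord]) -> list[PatientRecord]:
    return [
        r for r in cohort if r.nodes_examined >= 1 and r.nodes_positive >= 1
    ]


@dataclass
class GroupResult:
    label: str
    n: int
    fit: GompertzFit | None
    rs_curve: RelativeSurvivalCurve | None = None
    obs_curve: SurvivalCurve | None = None
    interval: tuple[float, float] | None = None  # %LN+ groups
    count_class: str | None = None  # LN-count groups


@dataclass
class ScanRow:
    cutoff: float
    n: int
    fit: GompertzFit | None
    skipped: bool = False

    @property
    def ip_years(self) -> float:
        return self.fit.ip_years if self.fit is not None else float("nan")


@dataclass
class PairwiseTest:
    group_a: str
    group_b: str
    month: int
    z: float
    p: float


@dataclass
class StratificationResult:
    groups: list[GroupResult]
    pairwise_tests: list[PairwiseTest] = field(default_factory=list)
    logrank_tests: list[tuple[str, str, float, float]] = field(default_factory=list)
    scan_table: list[ScanRow] = field(default_factory=list)
    seed: int = 0

    def group(self, label: str) -> GroupResult:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            f = g.fit
            rows.append(
                {
                    "group": g.label,
                    "n": g.n,
                    "b1": f.b1 if f else float("nan"),
                    "b2": f.b2 if f else float("nan"),
                    "b3": f.b3 if f else float("nan"),
                    "ip_years": f.ip_years if f else float("nan"),
                    "r_squared": f.r_squared if f else float("nan"),
                    "converged": f.converged if f else False,
                }
            )
        return pd.DataFrame(rows)

    def scan_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": [r.cutoff for r in self.scan_table],
                "n": [r.n for r in self.scan_table],
                "ip_years": [r.ip_years for r in self.scan_table],
                "skipped": [r.skipped for r in self.scan_table],
            }
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "groups": [
                {
                    "label": g.label,
                    "n": g.n,
                    "interval": g.interval,
                    "count_class": g.count_class,
                    "fit": g.fit.to_dict() if g.fit else None,
                }
                for g in self.groups
            ],
            "pairwise_tests": [
                {
                    "group_a": t.group_a,
                    "group_b": t.group_b,
                    "month": t.month,
                    "z": t.z,
                    "p": t.p,
                }
                for t in self.pairwise_tests
            ],
            "logrank_tests": [
                {"group_a": a, "group_b": b, "statistic": s, "p": p}
                for a, b, s, p in self.logrank_tests
            ],
            "scan_table": [
                {
                    "cutoff": r.cutoff,
                    "n": r.n,
                    "ip_years": r.ip_years,
                    "skipped": r.skipped,
                    "fit": r.fit.to_dict() if r.fit else None,
                }
                for r in self.scan_table
            ],
        }


def fit_group(
    records: Sequence[PatientRecord],
    life_table: LifeTable,
    max_months: int = 240,
    seed: int = 0,
    truncate_month: int | None = None,
):
    """Run one sub-cohort through the full curve pipeline:
    Ederer II -> Kaplan–Meier -> relative survival -> inverse Gompertz fit.

    Returns (fit, rs_curve, obs_curve, expected_curve).
    """
    expected = ederer2_expected(records, life_table, max_months)
    observed = km_estimate(records, max_months)
    rs = relative_survival(observed, expected)
    fit = fit_inverse_gompertz(rs, seed=seed, truncate_month=truncate_month)
    return fit, rs, observed, expected


def cutoff_scan(
    cohort: Sequence[PatientRecord],
    life_table: LifeTable,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    seed: int = 0,
    max_months: int = 240,
    min_group: int = MIN_GROUP_SIZE,
    truncate_month: int | None = None,
) -> list[ScanRow]:
    """Inflection point as a function of the %LN+ inclusion cutoff.

    For each cutoff c the sub-cohort of LN+ patients with %LN+ < c is run
    through the full pipeline; sub-cohorts smaller than ``min_group`` yield
    a skipped row instead of an unstable fit.
    """
    if any(not (0.0 < c <= 1.0) for c in cutoffs):
        raise ValueError("cutoffs must lie in (0, 1]")
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    base = _ln_positive_cohort(cohort)
    fracs = np.array([percent_ln_positive(r) for r in base])
    rows = []
    for c in cutoffs:
        sub = [r for r, f in zip(base, fracs) if f < c or (c == 1.0 and f <= 1.0)]
        if len(sub) < min_group:
            rows.append(ScanRow(float(c), len(sub), None, skipped=True))
            continue
        fit, *_ = fit_group(
            sub, life_table, max_months=max_months, seed=seed,
            truncate_month=truncate_month,
        )
        rows.append(ScanRow(float(c), len(sub), fit))
    return rows


def _interval_labels(boundaries: Sequence[float]) -> list[tuple[str, tuple[float, float]]]:
    edges = [0.0, *boundaries, 1.0]
    out = []
    for lo, hi in zip(edges, edges[1:]):
        if lo == 0.0:
            label = f"<{hi:.0%}"
        elif hi == 1.0:
            label = f">={lo:.0%}"
        else:
            label = f"{lo:.0%}-{hi:.0%}".replace("%-", "-")
        out.append((label, (lo, hi)))
    return out


def _pairwise_tests(groups: list[GroupResult], test_months: Sequence[int]):
    z_tests, lr_tests = [], []
    fitted = [g for g in groups if g.rs_curve is not None]
    for i, ga in enumerate(fitted):
        for gb in fitted[i + 1:]:
            for m in test_months:
                if m in ga.rs_curve.time_grid and m in gb.rs_curve.time_grid:
                    try:
                        t = rs_z_test(ga.rs_curve, gb.rs_curve, m)
                    except DegenerateTestError:
                        continue
                    z_tests.append(
                        PairwiseTest(ga.label, gb.label, m, t.z, t.p)
                    )
            try:
                lr = logrank_test(ga.records, gb.records)  # type: ignore[attr-defined]
                lr_tests.append((ga.label, gb.label, lr.statistic, lr.p))
            except DegenerateTestError:
                pass
    return z_tests, lr_tests


def stratify_groups(
    cohort: Sequence[PatientRecord],
    life_table: LifeTable,
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
    seed: int = 0,
    max_months: int = 240,
    test_months: Sequence[int] = DEFAULT_TEST_MONTHS,
    truncate_month: int | None = None,
) -> StratificationResult:
    """Three-group (in general, k+1-group) %LN+ stratification.

    Groups are half-open [low, high) with the top group closed at 1.0, so a
    patient at exactly the upper boundary (e.g. 40%) falls in the top
    group. Each group is run through the full pipeline; empty groups are
    reported with n=0 and no fit.
    """
    if list(boundaries) != sorted(boundaries) or any(
        not (0.0 < b < 1.0) for b in boundaries
    ):
        raise ValueError("boundaries must be sorted and inside (0, 1)")
    base = _ln_positive_cohort(cohort)
    fracs = np.array([percent_ln_positive(r) for r in base])
    groups = []
    for label, (lo, hi) in _interval_labels(boundaries):
        top = hi == 1.0
        members = [
            r
            for r, f in zip(base, fracs)
            if (lo <= f < hi) or (top and f == 1.0)
        ]
        g = _make_group(members, label, life_table, max_months, seed, truncate_month)
        g.interval = (lo, hi)
        groups.append(g)
    z_tests, lr_tests = _pairwise_tests(groups, test_months)
    return StratificationResult(groups, z_tests, lr_tests, seed=seed)


def stratify_by_ln_count(
    cohort: Sequence[PatientRecord],
    life_table: LifeTable,
    classes: Sequence[int] = (1, 2, 3),
    seed: int = 0,
    max_months: int = 240,
    test_months: Sequence[int] = DEFAULT_TEST_MONTHS,
    truncate_month: int | None = None,
) -> StratificationResult:
    """Stratify by absolute positive-node count: one class per count in
    ``classes`` plus a final open class ``>=max+1`` (default 1, 2, 3, >=4)."""
    if list(classes) != sorted(set(classes)) or any(c < 1 for c in classes):
        raise ValueError("classes must be distinct positive integers, ascending")
    base = _ln_positive_cohort(cohort)
    top = max(classes) + 1
    defs = [(str(c), lambda r, c=c: r.nodes_positive == c) for c in classes]
    defs.append((f">={top}", lambda r: r.nodes_positive >= top))
    groups = []
    for label, pred in defs:
        members = [r for r in base if pred(r)]
        g = _make_group(members, label, life_table, max_months, seed, truncate_month)
        g.count_class = label
        groups.append(g)
    z_tests, lr_tests = _pairwise_tests(groups, test_months)
    return StratificationResult(groups, z_tests, lr_tests, seed=seed)


def _make_group(
    members, label, life_table, max_months, seed, truncate_month
) -> GroupResult:
    if len(members) == 0:
        g = GroupResult(label, 0, None)
    else:
        fit, rs, obs, _ = fit_group(
            members, life_table, max_months=max_months, seed=seed,
            truncate_month=truncate_month,
        )
        g = GroupResult(label, len(members), fit, rs_curve=rs, obs_curve=obs)
    g.records = list(members)  # kept for log-rank tests
    return g
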