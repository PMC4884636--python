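"""Population expected-survival life tables and Ederer II expected survival.

A life table gives the annual probability of surviving one more year for a
member of the general population of given sex, race, attained age, and
calendar year. Expected survival for a cohort is computed with the
Ederer II convention: at every interval the expected survival is averaged
over the subjects *still at risk in the observed data*, so the matched
population shrinks with the cohort's own deaths and censorings.

The analysis grid is monthly. Annual probabilities are converted to
monthly ones under a constant hazard within the year
(``p_month = p_annual ** (1/12)``, the standard actuarial convention), and
attained age and calendar year advance together in whole years at 12-month
boundaries from diagnosis. Ages beyond the table's maximum fall back to the
maximum-age row (life-table closure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import LifeTableCoverageError
from .records import PatientRecord

logger = logging.getLogger(__name__)

_LIFETABLE_COLUMNS = ["sex", "race", "age", "year", "annual_survival"]


@dataclass
class ExpectedSurvivalCurve:
    """Cumulative expected survival on a monthly grid starting at month 0."""

    time_grid: np.ndarray  # months, 0..M
    values: np.ndarray  # cumulative probabilities, values[0] == 1

    def __post_init__(self):
        self.time_grid = np.asarray(self.time_grid, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.values[0] != 1.0:
            raise ValueError("expected survival must start at 1 at month 0")
        if np.any(np.diff(self.values) > 1e-12):
            raise ValueError("expected survival must be non-increasing")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("expected survival must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.time_grid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.time_grid, "expected_survival": self.values})


class LifeTable:
    """Annual survival probabilities on a rectangular
    (sex x race x age x calendar-year) grid.

    Lookups outside the declared race set, year range, or (below-minimum)
    age range raise :class:`LifeTableCoverageError`; ages above the maximum
    clamp to the maximum-age row.
    """

    def __init__(
        self,
        sexes: Sequence[str],
        races: Sequence[str],
        ages: Sequence[int],
        years: Sequence[int],
        values: np.ndarray,
    ):
        self.sexes = tuple(sexes)
        self.races = tuple(races)
        self.ages = np.asarray(ages, dtype=np.int64)
        self.years = np.asarray(years, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        expected_shape = (len(self.sexes), len(self.races), len(self.ages), len(self.years))
        if values.shape != expected_shape:
            raise ValueError(
                f"values shape {values.shape} does not match grid {expected_shape}"
            )
        if np.any((values < 0) | (values > 1)) or np.any(~np.isfinite(values)):
            raise ValueError("annual survival probabilities must lie in [0, 1]")
        if np.any(np.diff(self.ages) != 1) or np.any(np.diff(self.years) != 1):
            raise ValueError("age and year grids must be contiguous integer ranges")
        self.values = values
        self._sex_idx = {s: i for i, s in enumerate(self.sexes)}
        self._race_idx = {r: i for i, r in enumerate(self.races)}

    # -- lookups ----------------------------------------------------------

    def annual_survival(self, sex: str, race: str, age: int, year: int) -> float:
        if sex not in self._sex_idx or race not in self._race_idx:
            raise LifeTableCoverageError(sex, race, age, year)
        return float(
            self.annual_survival_array(
                np.array([self._sex_idx[sex]]),
                np.array([self._race_idx[race]]),
                np.array([age]),
                np.array([year]),
            )[0]
        )

    def annual_survival_array(
        self,
        sex_idx: np.ndarray,
        race_idx: np.ndarray,
        age: np.ndarray,
        year: np.ndarray,
    ) -> np.ndarray:
        """Vectorized lookup by pre-resolved sex/race indices and raw
        age/year values; clamps over-maximum ages, errors elsewhere."""
        age = np.asarray(age, dtype=np.int64)
        year = np.asarray(year, dtype=np.int64)
        if np.any(age > self.ages[-1]):
            logger.debug(
                "clamping %d age lookups to maximum table age %d",
                int(np.sum(age > self.ages[-1])),
                int(self.ages[-1]),
            )
        age = np.minimum(age, self.ages[-1])
        bad_age = age < self.ages[0]
        bad_year = (year < self.years[0]) | (year > self.years[-1])
        if np.any(bad_age | bad_year):
            i = int(np.argmax(bad_age | bad_year))
            raise LifeTableCoverageError(
                self.sexes[int(sex_idx[i])],
                self.races[int(race_idx[i])],
                int(np.asarray(age)[i]),
                int(year[i]),
            )
        return self.values[
            sex_idx, race_idx, age - self.ages[0], year - self.years[0]
        ]

    def resolve_indices(self, sexes, races, ages, years):
        """Map categorical sex/race sequences to integer index arrays."""
        try:
            si = np.array([self._sex_idx[s] for s in sexes], dtype=np.int64)
        except KeyError as e:
            raise LifeTableCoverageError(e.args[0], "?", -1, -1) from None
        try:
            ri = np.array([self._race_idx[r] for r in races], dtype=np.int64)
        except KeyError as e:
            bad = e.args[0]
            k = list(races).index(bad)
            raise LifeTableCoverageError(
                list(sexes)[k], bad, int(list(ages)[k]), int(list(years)[k])
            ) from None
        return si, ri

    # -- serialization ----------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        if list(df.columns) != _LIFETABLE_COLUMNS:
            raise ValueError(
                f"life-table CSV must have exactly columns {_LIFETABLE_COLUMNS}, "
                f"got {list(df.columns)}"
            )
        sexes = sorted(df["sex"].unique())
        races = sorted(df["race"].unique())
        ages = np.arange(df["age"].min(), df["age"].max() + 1)
        years = np.arange(df["year"].min(), df["year"].max() + 1)
        n_cells = len(sexes) * len(races) * len(ages) * len(years)
        if len(df) != n_cells or df.duplicated(["sex", "race", "age", "year"]).any():
            raise ValueError(
                "life table is not rectangular over sex x race x age x year"
            )
        pivot = df.set_index(["sex", "race", "age", "year"])["annual_survival"]
        values = pivot.sort_index().to_numpy().reshape(
            len(sexes), len(races), len(ages), len(years)
        )
        return cls(sexes, races, ages, years, values)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [self.sexes, self.races, self.ages, self.years],
            names=["sex", "race", "age", "year"],
        )
        return (
            pd.Series(self.values.ravel(), index=idx, name="annual_survival")
            .reset_index()
        )

    @classmethod
    def read_csv(cls, path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _monthly_expected_matrix(
    cohort: Sequence[PatientRecord],
    table: LifeTable,
    max_months: int,
    through_months: np.ndarray | None = None,
) -> np.ndarray:
    """P[i, j] = subject i's expected probability of surviving month interval
    j -> j+1, i.e. the annual probability at the attained (age, year) of the
    year containing interval j, to the power 1/12.

    If ``through_months`` is given, the table only needs to cover each
    subject through that many months of their own follow-up; entries beyond
    it are filled with 1.0 and must not be used by the caller.
    """
    n = len(cohort)
    sexes = [r.sex for r in cohort]
    races = [r.race for r in cohort]
    ages = np.array([r.age_at_dx for r in cohort], dtype=np.int64)
    years = np.array([r.dx_year for r in cohort], dtype=np.int64)
    si, ri = table.resolve_indices(sexes, races, ages, years)

    n_year_offsets = (max_months + 11) // 12
    annual = np.ones((n, n_year_offsets), dtype=float)
    for yo in range(n_year_offsets):
        if through_months is None:
            need = np.ones(n, dtype=bool)
        else:
            need = through_months > 12 * yo
        if not need.any():
            continue
        annual[need, yo] = table.annual_survival_array(
            si[need], ri[need], ages[need] + yo, years[need] + yo
        )
    monthly = annual ** (1.0 / 12.0)
    offsets = np.arange(max_months) // 12
    return monthly[:, offsets]


def ederer2_expected(
    cohort: Sequence[PatientRecord], table: LifeTable, max_months: int
) -> ExpectedSurvivalCurve:
    """Ederer II matched expected survival for a cohort on a monthly grid.

    For interval j (month j to j+1) the conditional expected interval
    survival is the mean of the individual monthly expected survival over
    subjects still at risk at month j in the observed data (follow-up of at
    least j+1 months). The curve is the running product of these interval
    means. If the at-risk set empties before ``max_months`` the curve is
    truncated at the last computable month.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if max_months < 1:
        raise ValueError("max_months must be >= 1")
    follow = np.array([r.follow_up_months for r in cohort], dtype=np.int64)
    P = _monthly_expected_matrix(cohort, table, max_months, through_months=follow)

    values = [1.0]
    acc = 1.0
    for j in range(max_months):
        at_risk = follow >= j + 1
        if not at_risk.any():
            break
        acc *= float(P[at_risk, j].mean())
        values.append(acc)
    m = len(values) - 1
    return ExpectedSurvivalCurve(np.arange(m + 1), np.array(values))
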