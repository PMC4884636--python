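"""Seeded synthetic registry cohorts with known relative-survival truth.

Real node-positive prostatectomy extracts come from population registries
and cannot be redistributed, so this module generates cohorts whose
statistical structure is known by construction: within each %LN+ stratum
the true relative survival follows the inverse Gompertz law
RS(t) = 1 - b1*exp(-b2*exp(-b3*t)), and each subject's overall survival is
the product of that law with the expected survival implied by a supplied
life table for the subject's own demographics. Death times are drawn from
this product by inverse-transform sampling on the monthly grid (linear
interpolation between grid points, then recorded at the whole month of
death, the registry convention). Censoring is the minimum of an
independent geometric dropout time and an administrative horizon.

Simulation truth must be a valid survival law, so ``b1_true`` is restricted
to (0, 1] even though *fitting* real curves may return b1 > 1.

The default cohort spec is a three-stratum world with true inflection
points of 25, 10 and 7 years for the <10%, 10-40% and >=40% strata; b2 is
taken from the published whole-cohort fits, b3 = ln(b2)/IP, and b1 is the
published value clamped into (0, 1]. Demographics match the published
whole-cohort composition. The administrative horizon is 312 months (the
maximum follow-up of a 1988 diagnosis at the registry's 2014 data
submission) and the dropout rate makes ~20% of subjects drop out before
the horizon.
"""

from __future__ import annotations

import configparser
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .life_tables import LifeTable, _monthly_expected_matrix
from .records import PatientRecord

#: Maximum follow-up of a 1988 diagnosis at a 2014 registry data submission.
DEFAULT_HORIZON_MONTHS = 312

#: Monthly geometric dropout rate giving ~20% total dropout by the horizon.
DEFAULT_CENSORING_RATE = 1.0 - 0.8 ** (1.0 / DEFAULT_HORIZON_MONTHS)

__all__ = [
    "StratumSpec",
    "Demographics",
    "CohortSpec",
    "generate_cohort",
    "default_cohort_spec",
    "synthetic_life_table",
]


@dataclass(frozen=True)
class StratumSpec:
    """One %LN+ stratum of the simulated world.

    ``ln_fraction_range`` is a half-open interval [low, high) of
    nodes_positive/nodes_examined (the top stratum may close at 1.0 via
    ``closed_top``); ``censoring_rate`` is the monthly probability of
    random dropout; ``horizon_months`` is the administrative censoring
    time.
    """

    label: str
    ln_fraction_range: tuple[float, float]
    n: int
    b1_true: float
    b2_true: float
    b3_true: float  # per year
    censoring_rate: float = DEFAULT_CENSORING_RATE
    horizon_months: int = DEFAULT_HORIZON_MONTHS
    closed_top: bool = False

    def __post_init__(self):
        lo, hi = self.ln_fraction_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"bad ln_fraction_range {self.ln_fraction_range}")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not (0.0 <= self.b1_true <= 1.0):
            raise ValueError(
                "b1_true must lie in [0, 1] so the simulated relative "
                "survival is a valid survival law (b1_true=0 means the "
                "stratum tracks expected survival exactly)"
            )
        if self.b2_true <= 0 or self.b3_true <= 0:
            raise ValueError("b2_true and b3_true must be positive")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.horizon_months < 1:
            raise ValueError("horizon_months must be >= 1")

    def contains(self, frac: float) -> bool:
        lo, hi = self.ln_fraction_range
        return (lo <= frac < hi) or (self.closed_top and frac == hi)

    def true_ip_years(self) -> float:
        return math.log(self.b2_true) / self.b3_true if self.b2_true > 1 else 0.0


@dataclass(frozen=True)
class Demographics:
    """Sampling distribution for (age, race, diagnosis year)."""

    age_mean: float = 62.48
    age_sd: float = 7.4
    age_range: tuple[int, int] = (35, 90)
    race_probs: tuple[tuple[str, float], ...] = (
        ("white", 0.8364),
        ("black", 0.1154),
        ("other", 0.0482),
    )
    year_range: tuple[int, int] = (1988, 2012)
    grade_probs: tuple[tuple[str, float], ...] = (
        ("I", 0.0071),
        ("II", 0.2094),
        ("III", 0.7661),
        ("IV", 0.0119),
        ("unknown", 0.0055),
    )
    radiation_probs: tuple[tuple[str, float], ...] = (
        ("no", 0.7615),
        ("yes", 0.2063),
        ("unknown", 0.0322),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a simulated cohort: strata plus shared
    demographic and nodal-sampling distributions and the master seed."""

    strata: tuple[StratumSpec, ...]
    demographics: Demographics = field(default_factory=Demographics)
    ln_examined_mean: float = 10.0  # examined nodes ~ 1 + Poisson(mean - 1)
    seed: int = 0

    def __post_init__(self):
        ivs = sorted(s.ln_fraction_range for s in self.strata)
        for (a_lo, a_hi), (b_lo, b_hi) in zip(ivs, ivs[1:]):
            if b_lo < a_hi:
                raise ValueError("stratum ln_fraction_ranges must be disjoint")
        if self.ln_examined_mean < 1:
            raise ValueError("ln_examined_mean must be >= 1")

    # flat key-value config round-trip, one stratum per section
    def to_config(self, path) -> None:
        cp = configparser.ConfigParser()
        d = self.demographics
        cp["cohort"] = {
            "seed": str(self.seed),
            "ln_examined_mean": str(self.ln_examined_mean),
            "age_mean": str(d.age_mean),
            "age_sd": str(d.age_sd),
            "age_range": f"{d.age_range[0]},{d.age_range[1]}",
            "year_range": f"{d.year_range[0]},{d.year_range[1]}",
            "race_probs": ";".join(f"{k}:{v}" for k, v in d.race_probs),
            "grade_probs": ";".join(f"{k}:{v}" for k, v in d.grade_probs),
            "radiation_probs": ";".join(f"{k}:{v}" for k, v in d.radiation_probs),
        }
        for s in self.strata:
            cp[f"stratum:{s.label}"] = {
                "ln_fraction_low": str(s.ln_fraction_range[0]),
                "ln_fraction_high": str(s.ln_fraction_range[1]),
                "closed_top": str(s.closed_top),
                "n": str(s.n),
                "b1_true": str(s.b1_true),
                "b2_true": str(s.b2_true),
                "b3_true": str(s.b3_true),
                "censoring_rate": str(s.censoring_rate),
                "horizon_months": str(s.horizon_months),
            }
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_config(cls, path) -> "CohortSpec":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        c = cp["cohort"]

        def _probs(s):
            return tuple(
                (k, float(v)) for k, v in (kv.split(":") for kv in s.split(";"))
            )

        demo = Demographics(
            age_mean=float(c["age_mean"]),
            age_sd=float(c["age_sd"]),
            age_range=tuple(int(x) for x in c["age_range"].split(",")),
            year_range=tuple(int(x) for x in c["year_range"].split(",")),
            race_probs=_probs(c["race_probs"]),
            grade_probs=_probs(c["grade_probs"]),
            radiation_probs=_probs(c["radiation_probs"]),
        )
        strata = []
        for name in cp.sections():
            if not name.startswith("stratum:"):
                continue
            s = cp[name]
            strata.append(
                StratumSpec(
                    label=name.split(":", 1)[1],
                    ln_fraction_range=(
                        float(s["ln_fraction_low"]),
                        float(s["ln_fraction_high"]),
                    ),
                    closed_top=s.getboolean("closed_top"),
                    n=int(s["n"]),
                    b1_true=float(s["b1_true"]),
                    b2_true=float(s["b2_true"]),
                    b3_true=float(s["b3_true"]),
                    censoring_rate=float(s["censoring_rate"]),
                    horizon_months=int(s["horizon_months"]),
                )
            )
        return cls(
            strata=tuple(strata),
            demographics=demo,
            ln_examined_mean=float(c["ln_examined_mean"]),
            seed=int(c["seed"]),
        )


def default_cohort_spec(
    n_per_stratum: int = 2000,
    seed: int = 0,
    censoring_rate: float = DEFAULT_CENSORING_RATE,
    horizon_months: int = DEFAULT_HORIZON_MONTHS,
) -> CohortSpec:
    """The package's stated simulation world: three %LN+ strata with true
    inflection points 25 / 10 / 7 years and survival worsening with %LN+.

    b2 per stratum is the published whole-cohort estimate, b3 = ln(b2)/IP,
    and b1 is the published estimate clamped into (0, 1] so the truth is a
    valid survival law.
    """
    strata = (
        StratumSpec(
            "<10%", (0.0, 0.10), n_per_stratum,
            b1_true=1.0, b2_true=9.016, b3_true=math.log(9.016) / 25.0,
            censoring_rate=censoring_rate, horizon_months=horizon_months,
        ),
        StratumSpec(
            "10-40%", (0.10, 0.40), n_per_stratum,
            b1_true=0.337, b2_true=6.15, b3_true=math.log(6.15) / 10.0,
            censoring_rate=censoring_rate, horizon_months=horizon_months,
        ),
        StratumSpec(
            ">=40%", (0.40, 1.0), n_per_stratum, closed_top=True,
            b1_true=0.469, b2_true=4.51, b3_true=math.log(4.51) / 7.0,
            censoring_rate=censoring_rate, horizon_months=horizon_months,
        ),
    )
    return CohortSpec(strata=strata, seed=seed)


def synthetic_life_table(
    age_range: tuple[int, int] = (30, 110),
    year_range: tuple[int, int] = (1988, 2040),
    races: Sequence[str] = ("white", "black", "other"),
) -> LifeTable:
    """Gompertz–Makeham male general-population mortality, with small race
    multipliers and a mild secular improvement.

    Annual hazard h(age, year) = (A + B*exp(theta*age)) * race_mult *
    0.997^(year-1988); annual survival exp(-h). Gives ~1.3%/yr mortality at
    age 62, a plausible US male level.
    """
    A, B, theta = 2e-4, 5e-5, 0.09
    race_mult = {"white": 1.0, "black": 1.25, "other": 0.9}
    ages = np.arange(age_range[0], age_range[1] + 1)
    years = np.arange(year_range[0], year_range[1] + 1)
    hazard_age = A + B * np.exp(theta * ages)  # (n_ages,)
    secular = 0.997 ** (years - years[0])  # (n_years,)
    values = np.empty((1, len(races), len(ages), len(years)))
    for k, race in enumerate(races):
        h = race_mult.get(race, 1.0) * hazard_age[:, None] * secular[None, :]
        values[0, k] = np.exp(-h)
    return LifeTable(("male",), tuple(races), ages, years, values)


def _sample_node_counts(rng: np.random.Generator, stratum: StratumSpec, mean: float):
    """Draw (examined, positive) with positive/examined in the stratum range
    and positive >= 1, by joint rejection over the examined-count draw."""
    lo, hi = stratum.ln_fraction_range
    for _ in range(10000):
        examined = 1 + rng.poisson(mean - 1.0)
        ks = np.arange(1, examined + 1)
        frac = ks / examined
        ok = (frac >= lo) & ((frac < hi) | (stratum.closed_top & (frac == hi)))
        valid = ks[ok]
        if len(valid):
            return int(examined), int(rng.choice(valid))
    raise RuntimeError(
        f"could not draw node counts in range {stratum.ln_fraction_range}; "
        "is the examined-count distribution compatible with the stratum?"
    )


def generate_cohort(spec: CohortSpec, life_table: LifeTable) -> list[PatientRecord]:
    """Generate the cohort described by ``spec`` against ``life_table``.

    Deterministic given (spec, life_table): the same spec (including its
    seed) always yields byte-identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    demo = spec.demographics
    records: list[PatientRecord] = []
    pid = 0
    for stratum in spec.strata:
        n = stratum.n
        if n == 0:
            continue
        ages = np.clip(
            np.round(rng.normal(demo.age_mean, demo.age_sd, size=n)),
            demo.age_range[0],
            demo.age_range[1],
        ).astype(np.int64)
        races = rng.choice(
            [k for k, _ in demo.race_probs],
            size=n,
            p=[v for _, v in demo.race_probs],
        )
        years = rng.integers(demo.year_range[0], demo.year_range[1] + 1, size=n)
        grades = rng.choice(
            [k for k, _ in demo.grade_probs],
            size=n,
            p=np.array([v for _, v in demo.grade_probs])
            / sum(v for _, v in demo.grade_probs),
        )
        radiation = rng.choice(
            [k for k, _ in demo.radiation_probs],
            size=n,
            p=np.array([v for _, v in demo.radiation_probs])
            / sum(v for _, v in demo.radiation_probs),
        )
        node_counts = [
            _sample_node_counts(rng, stratum, spec.ln_examined_mean) for _ in range(n)
        ]

        horizon = stratum.horizon_months
        # Expected survival per subject on the monthly grid, then overall
        # S(m) = S_expected(m) * RS_true(m/12).
        proto = [
            PatientRecord(
                patient_id=str(i), age_at_dx=int(a), sex="male", race=str(r),
                dx_year=int(y), follow_up_months=horizon, vital_status="censored",
                nodes_examined=ne, nodes_positive=npos, grade=str(g),
                radiation=str(rd),
            )
            for i, (a, r, y, g, rd, (ne, npos)) in enumerate(
                zip(ages, races, years, grades, radiation, node_counts)
            )
        ]
        P = _monthly_expected_matrix(proto, life_table, horizon)
        S_exp = np.cumprod(P, axis=1)  # S at months 1..horizon
        # evaluated inline so b1_true = 0 (tracks expected survival) is valid
        t_years = np.arange(1, horizon + 1) / 12.0
        rs_true = 1.0 - stratum.b1_true * np.exp(
            -stratum.b2_true * np.exp(-stratum.b3_true * t_years)
        )
        S = np.hstack([np.ones((n, 1)), S_exp * rs_true[None, :]])  # months 0..horizon

        u = rng.uniform(size=n)
        death_month = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
        for i in range(n):
            si = S[i]
            if u[i] < si[-1]:
                continue  # survives past the simulated grid
            m = int(np.argmax(si <= u[i]))  # first month with S <= u
            # linear interpolation between grid points, then whole-month
            # discretization (death recorded at the month it occurs in)
            s_prev, s_cur = si[m - 1], si[m]
            t_star = m - 1 + (s_prev - u[i]) / (s_prev - s_cur) if s_prev > s_cur else m
            death_month[i] = max(1, math.ceil(t_star - 1e-12))

        if stratum.censoring_rate > 0:
            dropout = rng.geometric(stratum.censoring_rate, size=n)
        else:
            dropout = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
        censor_month = np.minimum(dropout, horizon)
        dead = death_month <= censor_month  # death wins ties (recorded first)
        follow = np.where(dead, death_month, censor_month)

        for i, rec in enumerate(proto):
            records.append(
                PatientRecord(
                    patient_id=f"S{pid + i:06d}",
                    age_at_dx=rec.age_at_dx,
                    sex=rec.sex,
                    race=rec.race,
                    dx_year=rec.dx_year,
                    follow_up_months=int(follow[i]),
                    vital_status="dead" if dead[i] else "censored",
                    nodes_examined=rec.nodes_examined,
                    nodes_positive=rec.nodes_positive,
                    grade=rec.grade,
                    radiation=rec.radiation,
                )
            )
        pid += n
    return records
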