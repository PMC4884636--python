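"""Patient-level registry records and their CSV serialization.

A :class:`PatientRecord` is one subject from a SEER-style registry extract:
demographics at diagnosis, follow-up in whole months, vital status at last
contact, and the nodal pathology counts (nodes examined at surgery, nodes
found positive) from which percent nodal involvement (%LN+) is derived.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataIntegrityError

SEXES = ("male",)
RACES = ("white", "black", "other")
GRADES = ("I", "II", "III", "IV", "unknown")
RADIATION = ("yes", "no", "unknown")
VITAL_STATUS = ("dead", "censored")

#: Column order used for cohort CSV files; exactly the record field names.
FIELD_NAMES = (
    "patient_id",
    "age_at_dx",
    "sex",
    "race",
    "dx_year",
    "follow_up_months",
    "vital_status",
    "nodes_examined",
    "nodes_positive",
    "grade",
    "radiation",
)


@dataclass
class PatientRecord:
    """One registry subject.

    ``follow_up_months`` is the number of whole months from diagnosis
    (here, surgery) to death or last contact; ``vital_status`` says which.
    """

    patient_id: str
    age_at_dx: int
    sex: str
    race: str
    dx_year: int
    follow_up_months: int
    vital_status: str
    nodes_examined: int
    nodes_positive: int
    grade: str
    radiation: str

    def __post_init__(self):
        if self.sex not in SEXES:
            raise DataIntegrityError(f"unknown sex {self.sex!r}")
        if self.race not in RACES:
            raise DataIntegrityError(f"unknown race {self.race!r}")
        if self.grade not in GRADES:
            raise DataIntegrityError(f"unknown grade {self.grade!r}")
        if self.radiation not in RADIATION:
            raise DataIntegrityError(f"unknown radiation flag {self.radiation!r}")
        if self.vital_status not in VITAL_STATUS:
            raise DataIntegrityError(
                f"vital_status must be one of {VITAL_STATUS}, got "
                f"{self.vital_status!r}"
            )
        if self.follow_up_months < 0:
            raise DataIntegrityError("follow_up_months must be non-negative")
        if self.nodes_examined < 0 or self.nodes_positive < 0:
            raise DataIntegrityError("node counts must be non-negative")
        if self.nodes_positive > self.nodes_examined:
            raise DataIntegrityError(
                f"nodes_positive ({self.nodes_positive}) exceeds nodes_examined "
                f"({self.nodes_examined}) for patient {self.patient_id!r}"
            )

    @property
    def is_dead(self) -> bool:
        return self.vital_status == "dead"


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tabulate a cohort, one row per subject, columns in canonical order."""
    return pd.DataFrame(
        [[getattr(r, f) for f in FIELD_NAMES] for r in cohort],
        columns=list(FIELD_NAMES),
    )


def frame_to_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    missing = set(FIELD_NAMES) - set(df.columns)
    if missing:
        raise DataIntegrityError(f"cohort table missing columns: {sorted(missing)}")
    int_fields = {f.name for f in fields(PatientRecord) if f.type == "int"}
    out = []
    for row in df[list(FIELD_NAMES)].itertuples(index=False):
        kwargs = {
            name: (int(val) if name in int_fields else str(val))
            for name, val in zip(FIELD_NAMES, row)
        }
        out.append(PatientRecord(**kwargs))
    return out


def write_cohort_csv(cohort: Sequence[PatientRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    return frame_to_cohort(pd.read_csv(path, dtype={"patient_id": str}))


def event_arrays(cohort: Iterable[PatientRecord]):
    """(follow_up_months, event_indicator) as numpy arrays, the inputs of
    every nonparametric survival computation here."""
    import numpy as np

    recs = list(cohort)
    t = np.array([r.follow_up_months for r in recs], dtype=np.int64)
    d = np.array([r.is_dead for r in recs], dtype=bool)
    return t, d
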