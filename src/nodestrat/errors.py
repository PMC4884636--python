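"""Exception types shared across the pipeline."""


class NodestratError(Exception):
    """Base class for all package-specific errors."""


class LifeTableCoverageError(NodestratError, KeyError):
    """A required (sex, race, age, year) cell is missing from the life table."""

    def __init__(self, sex: str, race: str, age: int, year: int):
        self.cell = (sex, race, age, year)
        super().__init__(
            f"life table does not cover cell sex={sex!r}, race={race!r}, "
            f"age={age}, year={year}"
        )


class GridAlignmentError(NodestratError, ValueError):
    """Observed and expected survival curves live on incompatible time grids."""


class UndefinedRatioError(NodestratError, ZeroDivisionError):
    """Relative survival is undefined: expected survival reached 0 while the
    observed curve is still positive."""


class DegenerateTestError(NodestratError, ValueError):
    """A significance test has no sampling variability to test against
    (e.g. both standard errors zero with unequal values, or no events)."""


class InsufficientDataError(NodestratError, ValueError):
    """Too few curve points to identify the model parameters."""


class DataIntegrityError(NodestratError, ValueError):
    """A record violates a structural invariant (e.g. more positive than
    examined nodes)."""
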