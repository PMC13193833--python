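"""Exception hierarchy for cohort construction and analysis."""


class PnetCohortError(Exception):
    """Base class for all package errors."""


class SchemaError(PnetCohortError):
    """An input table is missing a required column or has an invalid layout."""


class EmptyTableError(PnetCohortError):
    """An input table contains no data rows after filtering."""


class JoinError(PnetCohortError):
    """Sample records reference patients absent from the patient table."""

    def __init__(self, message: str, offenders=()):
        super().__init__(message)
        self.offenders = list(offenders)


class EmptyPanelError(PnetCohortError):
    """A gene panel is empty after normalization/filtering or intersection."""


class ConfigError(PnetCohortError):
    """A synthetic-cohort or pipeline configuration is infeasible or invalid."""


class RegressionError(PnetCohortError):
    """The regression design cannot be built or fitted."""
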