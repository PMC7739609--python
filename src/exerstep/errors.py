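"""Exception hierarchy for the exerstep package."""


class ExerstepError(Exception):
    """Base class for all package-specific errors."""


class EmptyRecording(ExerstepError):
    """A trajectory file contains no frames."""


class MarkerSetMismatch(ExerstepError):
    """A required marker is absent (after alias resolution)."""


class FormatError(ExerstepError):
    """A file could not be parsed (bad rate, malformed columns, ...)."""


class InsufficientData(ExerstepError):
    """A series is too short for the requested computation."""


class ScheduleInfeasible(ExerstepError):
    """Game settings cannot accommodate the requested object schedule."""


class ConfigError(ExerstepError):
    """Invalid configuration (non-positive lengths, bad ranges, ...)."""


class LogParseError(ExerstepError):
    """A game event log record is malformed."""


class UndefinedRate(ExerstepError):
    """A per-trial rate was requested with zero valid trials."""


class DegenerateTable(ExerstepError):
    """A contingency table has a zero margin."""


class DuplicateRow(ExerstepError):
    """Two metric rows share the same (participant, condition, side, metric) key."""


class UndefinedMean(ExerstepError):
    """A pooled mean was requested from an empty group list."""


class TestUnavailable(ExerstepError):
    """Effect tests requested from a non-converged model fit."""

    __test__ = False    # keep pytest from collecting this as a test class


class RunFailed(ExerstepError):
    """A pipeline run produced no usable trials."""
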