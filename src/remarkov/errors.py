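"""Exception hierarchy. Every validation failure names the offending field path."""

from __future__ import annotations


class RemarkovError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RemarkovError):
    """A configuration document is missing a field or is structurally wrong."""

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        super().__init__(f"{field}: {message}" if field else message)


class ValidationError(RemarkovError):
    """A parameter value violates an invariant (bounds, ordering, coverage)."""

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        super().__init__(f"{field}: {message}" if field else message)


class CoverageError(ValidationError):
    """The life table does not cover every age the model visits."""


class BandLookupError(RemarkovError, KeyError):
    """A cost band was requested that does not exist for (strategy, state)."""


class InfeasibleMomentsError(RemarkovError, ValueError):
    """Requested (mean, se) cannot be matched by the requested distribution."""


class CalibrationFailure(RemarkovError):
    """The calibration objective could not be evaluated anywhere."""
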