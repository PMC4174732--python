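"""Exception hierarchy.

All package-specific failures derive from :class:`IsochronError` so callers
(and the CLI exit-code mapping) can distinguish validation problems from
runtime failures.
"""


class IsochronError(Exception):
    """Base class for all package errors."""


class ValidationError(IsochronError, ValueError):
    """Invalid argument, configuration, or malformed input data."""


class InsufficientDataError(IsochronError, ValueError):
    """A statistic was requested on a series too short to support it."""


class ExtractionError(IsochronError, RuntimeError):
    """Interval extraction from an accelerometer trace failed."""


class FitError(IsochronError, RuntimeError):
    """A model fit did not converge or was requested on unusable data."""
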