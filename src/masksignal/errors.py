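"""Exception hierarchy.

All errors raised by this package derive from :class:`MaskSignalError` so
callers can catch one base class; validation problems additionally derive
from :class:`ValueError` so plain-Python callers behave as expected.
"""


class MaskSignalError(Exception):
    """Base class for all package errors."""


class ValidationError(MaskSignalError, ValueError):
    """Invalid parameter value or malformed domain object."""


class RangeError(ValidationError):
    """A physical quantity is outside the sensor's operating range."""


class SessionParseError(MaskSignalError, ValueError):
    """A session file could not be parsed against the documented schema."""


class AlignmentError(SessionParseError):
    """Channels in a session file cannot be aligned to one clock."""
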