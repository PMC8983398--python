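"""Exception hierarchy.

Every error raised by the library derives from :class:`ClonotrackError` so
pipeline code can distinguish domain failures from programming errors.
"""


class ClonotrackError(Exception):
    """Base class for all clonotrack errors."""


class ConfigurationError(ClonotrackError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(ClonotrackError):
    """Malformed input table (e.g. a missing mandatory column)."""


class JoinError(ClonotrackError):
    """GEX/VDJ join attempted across mismatched samples."""


class DataError(ClonotrackError):
    """Input data unusable for the requested computation."""


class LookupFailure(ClonotrackError, KeyError):
    """Requested key/individual/time point/gene not present."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class InsufficientSeriesError(DataError):
    """Operation requires more time points or replicates than supplied."""


class SchemeMismatchError(ClonotrackError):
    """Clonotype sets built under different keying schemes were combined."""
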