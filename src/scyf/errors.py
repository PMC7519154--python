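"""Exception hierarchy for the SCyF codec.

Every error raised on a user-facing path derives from :class:`ScyfError`,
so callers (and the CLI) can catch one type and exit cleanly.
"""


class ScyfError(Exception):
    """Base class for all codec errors."""


class InvalidInputError(ScyfError):
    """Malformed numeric input (empty array, NaN samples, length mismatch)."""


class ConfigurationError(ScyfError):
    """Inconsistent codec configuration or signal too short for it."""


class MissingAnnotationError(ScyfError):
    """Neither explicit cycle bounds nor P-wave onsets were provided."""


class InternalError(ScyfError):
    """Invariant violation inside the codec (e.g. empty domain pool)."""


class EncodingError(ScyfError):
    """A field does not fit its fixed-width slot in the bitstream."""


class FormatError(ScyfError):
    """Byte string is not a SCyF container (bad magic)."""


class VersionError(ScyfError):
    """Container version not supported by this decoder."""


class CorruptStreamError(ScyfError):
    """Container is truncated or internally inconsistent."""


class UnsupportedFormatError(ScyfError):
    """Requested an input/output format this build does not read."""
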