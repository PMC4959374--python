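"""Exception hierarchy for the adlike pipeline.

Every error raised on a user-facing path derives from :class:`AdlikeError`
so callers (and the CLI) can catch one base class.
"""


class AdlikeError(Exception):
    """Base class for all adlike errors."""


class MontageError(AdlikeError):
    """Channel labels do not match the expected electrode montage."""


class ParseError(AdlikeError):
    """A file could not be parsed (bad cell, malformed document, ...)."""


class ValidationError(AdlikeError):
    """A domain object violates one of its invariants."""


class ParameterError(AdlikeError):
    """An operation was called with an out-of-range parameter."""


class ConfigError(AdlikeError):
    """A configuration document failed schema validation.

    The message names the dotted key path of the offending entry.
    """


class RecordingQualityError(AdlikeError):
    """Too much of a recording is artifact-contaminated to analyse."""


class DegenerateWindowError(AdlikeError):
    """A window has too few clean samples to compute statistics."""


class UndefinedIndexError(AdlikeError):
    """The Z-index is undefined (zero session variance or N < 2)."""


class SchemaMismatchError(AdlikeError):
    """Model and feature matrix were built under different feature schemas."""
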