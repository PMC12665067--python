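"""Exception hierarchy shared across the pipeline.

All errors derive from :class:`SeedSpatialError` so callers (and the CLI)
can distinguish configuration problems, malformed data and degenerate
inputs from genuine bugs.
"""


class SeedSpatialError(Exception):
    """Base class for all package errors."""


class ConfigError(SeedSpatialError):
    """Invalid pipeline configuration (unknown key, bad value)."""


class GemFormatError(SeedSpatialError):
    """A GEM table violates the expected format."""


class ParameterError(SeedSpatialError, ValueError):
    """An operation parameter is outside its valid range."""


class EmptyInputError(SeedSpatialError):
    """An operation received an empty table where data is required."""


class EmptyResultError(SeedSpatialError):
    """An operation removed everything (e.g. a filter threshold too high)."""


class SizingError(SeedSpatialError):
    """A synthetic section is too small to host the requested geometry."""


class DomainError(SeedSpatialError, ValueError):
    """A coordinate lies outside the section bounds."""
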