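"""Exception types shared across the pipeline."""


class PhotoavoidError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PhotoavoidError):
    """An input file does not conform to the documented column schema."""


class ValidationError(PhotoavoidError):
    """In-memory data violates an invariant (NaN sample, non-monotone time, ...)."""


class ConfigError(PhotoavoidError):
    """A configuration value is out of range or inconsistent."""


class DegenerateFitError(PhotoavoidError):
    """A regression problem is degenerate (e.g. constant reference channel)."""


class GenerationError(PhotoavoidError):
    """The synthetic generator was asked for something it cannot produce."""


class AlignmentError(PhotoavoidError):
    """Two traces that must share a time base do not."""
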