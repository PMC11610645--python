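"""Exception hierarchy.

Every error raised by this package derives from :class:`StygoscaleError`,
so callers can catch one base class at pipeline level.
"""


class StygoscaleError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StygoscaleError, ValueError):
    """An invalid configuration value (dimensions, proportions, shapes...)."""


class GenerationError(StygoscaleError, RuntimeError):
    """Synthetic-data generation failed (e.g. infeasible site packing)."""


class GeometryError(StygoscaleError, ValueError):
    """Raster/site geometry mismatch or out-of-bounds access."""


class ExtractionError(StygoscaleError, ValueError):
    """Land-use extraction over an empty or invalid buffer region."""


class ClassificationError(StygoscaleError, ValueError):
    """A raster code without a class mapping."""

    def __init__(self, message: str, offending_codes=()):
        super().__init__(message)
        self.offending_codes = tuple(offending_codes)


class DegenerateResponseError(StygoscaleError, ValueError):
    """A model response with a single class (all 0 or all 1)."""


class FitError(StygoscaleError, RuntimeError):
    """A model fit failed structurally (rank deficiency, bad family...)."""
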