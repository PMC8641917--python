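"""Exception hierarchy shared across the package.

All errors raised by glycoadhesion derive from :class:`GlycoadhesionError`,
so callers can catch one base class. The CLI maps the three broad families
(configuration, input, numeric/estimate) to distinct exit codes.
"""


class GlycoadhesionError(Exception):
    """Base class for all package errors."""


class ConfigError(GlycoadhesionError):
    """Invalid or inconsistent analysis configuration."""


class MalformedInputError(GlycoadhesionError):
    """A file or table violates the documented format."""


class StructuralError(GlycoadhesionError):
    """Internally inconsistent data (particle counts, frame grids, ...)."""


class UsageError(GlycoadhesionError):
    """An operation was called with arguments outside its contract."""


class UndefinedEstimateError(GlycoadhesionError):
    """An estimate is requested from data that cannot define it."""


class GeometryError(GlycoadhesionError):
    """Physically impossible geometry (crossed membranes, non-positive gap)."""


class NumericError(GlycoadhesionError):
    """Non-finite input or a divergent formula evaluation."""
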