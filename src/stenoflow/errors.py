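"""Exception hierarchy shared across the package."""


class StenoflowError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StenoflowError, ValueError):
    """Invalid configuration (e.g. a parameter range with min > max)."""


class GeometryError(StenoflowError, ValueError):
    """Degenerate or unusable vessel geometry (e.g. closed lumen)."""


class DomainError(StenoflowError, ValueError):
    """A query outside the geometric domain (arc length off-branch, point outside lumen)."""


class UndefinedMetricError(StenoflowError, ValueError):
    """An error metric whose definition degenerates on the given data."""
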