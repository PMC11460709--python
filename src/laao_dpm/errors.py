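"""Exception hierarchy shared across the pipeline."""


class LaaoDpmError(Exception):
    """Base class for all package errors."""


class ValidationError(LaaoDpmError, ValueError):
    """A specification or parameter violates its invariants.

    The message names the offending field.
    """


class GeometryError(LaaoDpmError, ValueError):
    """Degenerate or inconsistent geometric input."""


class PlacementError(LaaoDpmError, ValueError):
    """Device deployment outside the admissible range."""


class ConfigurationError(LaaoDpmError, ValueError):
    """Missing labels, landmarks, or configuration entries."""


class ConsistencyError(LaaoDpmError, ValueError):
    """Two inputs (e.g. mesh and field) do not cover the same domain."""


class OutOfDomainError(LaaoDpmError, ValueError):
    """A query point lies outside the spatial or temporal support."""


class CoverageError(LaaoDpmError, ValueError):
    """A time series does not span the required analysis window."""


class EmptyRegionError(LaaoDpmError, ValueError):
    """A region selector matched no sample points."""


class OutOfRangeError(LaaoDpmError, ValueError):
    """A lookup key falls outside the tabulated range."""
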