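"""Exception hierarchy.

Everything derives from :class:`VinegcError` so callers can catch the
package's failures with one clause; the leaves also subclass ``ValueError``
because they all signal bad inputs of one kind or another.
"""


class VinegcError(Exception):
    """Base class for all vinegc errors."""


class InvalidInputError(VinegcError, ValueError):
    """An argument violates an operation's preconditions."""


class ConfigurationError(VinegcError, ValueError):
    """Site or filter parameters are internally inconsistent."""


class NonInvertibleError(VinegcError, ValueError):
    """Penman-Monteith inversion denominator is non-positive: the supplied
    transpiration exceeds the energy/advection bound for these inputs."""


class InsufficientDataError(VinegcError, ValueError):
    """Too few records for the requested statistic."""


class UndefinedMetricError(VinegcError, ValueError):
    """The metric is mathematically undefined for this input (zero mean,
    constant series, zero pooled variance, ...)."""


class EmptySeriesError(VinegcError, ValueError):
    """An operation that needs records received none."""


class SchemaError(VinegcError, ValueError):
    """A CSV table does not conform to the expected column schema."""
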