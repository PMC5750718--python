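"""Exception hierarchy for vispop.

All vispop errors derive from :class:`VispopError` so callers can catch the
package's failures without swallowing unrelated bugs.
"""


class VispopError(Exception):
    """Base class for all vispop errors."""


class DomainError(VispopError, ValueError):
    """An input lies outside the mathematical domain of a model
    (e.g. a negative eccentricity)."""


class ExtrapolationError(DomainError):
    """An eccentricity falls outside the anchor range of an interpolation
    table and extrapolation was not explicitly enabled."""


class UndefinedRatioError(VispopError, ZeroDivisionError):
    """An expansion ratio was requested against a zero upstream count."""


class ConfigError(VispopError, ValueError):
    """A configuration value, key, or mode is invalid."""
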