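"""Exception hierarchy shared across the package."""


class BetascapeError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(BetascapeError, ValueError):
    """A generator or grid specification violates its invariants."""


class GridMismatchError(BetascapeError, ValueError):
    """Two gridded objects do not share the same geometry."""


class GeometryError(BetascapeError, ValueError):
    """A species range geometry is empty or invalid."""


class UnknownCladeError(BetascapeError, KeyError):
    """A clade label matches no species in the matrix."""


class UndefinedStatisticError(BetascapeError, ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class ConfigError(BetascapeError, ValueError):
    """A pipeline configuration is malformed or contains unknown keys."""
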