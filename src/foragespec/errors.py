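"""Exception hierarchy shared across the package."""


class ForagespecError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ForagespecError, ValueError):
    """Non-finite coordinates, bad parameter values, malformed records."""


class UndefinedBearingError(ForagespecError, ValueError):
    """Bearing requested between coincident points."""


class InsufficientDataError(ForagespecError, ValueError):
    """Too few observations for the statistic to be defined."""


class UndefinedStatisticError(ForagespecError, ValueError):
    """Statistic undefined for these values (e.g. CV with zero mean)."""


class NestingViolationError(ForagespecError, ValueError):
    """Trip labels not nested within individuals."""


class DegenerateDiveError(ForagespecError, ValueError):
    """A dive with fewer than two samples."""


class CollinearityError(ForagespecError, ValueError):
    """Covariate has no variation."""


class SchemaError(ForagespecError, ValueError):
    """A required column is missing from an input table."""


class ConfigError(ForagespecError, ValueError):
    """Invalid simulation or pipeline configuration."""
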