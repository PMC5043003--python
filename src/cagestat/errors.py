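"""Exception hierarchy shared across the package."""


class CagestatError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CagestatError):
    """An input table is missing mandatory columns or has the wrong layout."""


class ConsistencyError(CagestatError):
    """An input table violates an internal invariant (duplicate keys,
    a cage mapped to two groups, ...)."""


class DomainError(CagestatError, ValueError):
    """A numeric argument lies outside the domain of a formula."""


class ConfigurationError(CagestatError):
    """A design or simulation configuration is incomplete or inconsistent."""


class DegenerateComparisonError(CagestatError):
    """A comparison cannot be expressed on the SES scale (zero pooled SD
    with unequal means: the standardized effect is unbounded)."""


class RankError(CagestatError):
    """A model design matrix is rank deficient; the message names the
    aliased column."""
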