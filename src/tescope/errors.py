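"""Exception hierarchy shared across the toolkit."""


class TescopeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TescopeError):
    """A file does not conform to its expected on-disk format."""


class IntegrityError(TescopeError):
    """Parsed data violate an internal invariant (duplicates, negative counts, ...)."""


class ConfigError(TescopeError):
    """A configuration or parameter value is out of its admissible range."""


class InputError(TescopeError):
    """Arguments to an operation violate its preconditions."""


class UndefinedStatisticError(InputError):
    """A statistic is undefined for the given input (e.g. zero variance everywhere)."""


class DegenerateDesignError(InputError):
    """A regression design matrix is rank-deficient."""
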