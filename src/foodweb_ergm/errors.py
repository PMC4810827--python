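"""Exception hierarchy."""


class FoodWebError(Exception):
    """Base class for all package errors."""


class ValidationError(FoodWebError):
    """A food web violates a structural invariant (self-loop, duplicate label, ...)."""


class ParseError(FoodWebError):
    """A file could not be parsed under the declared dialect."""


class ConfigurationError(FoodWebError):
    """An unknown or ill-formed configuration statistic was requested."""


class ParameterError(FoodWebError):
    """A parameter vector is non-finite or misaligned with its model."""


class DegeneracyError(FoodWebError):
    """An ERGM placed essentially all probability mass on empty or complete graphs."""


class ComparisonError(FoodWebError):
    """Two fits cannot be compared (no shared configurations, different systems)."""
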