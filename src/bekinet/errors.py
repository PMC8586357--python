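"""Typed exceptions shared across the package."""


class BekinetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BekinetError, ValueError):
    """A parameter or record failed validation."""


class DomainError(BekinetError, ValueError):
    """Inputs are individually valid but violate a required inequality."""


class ConsistencyError(BekinetError, ValueError):
    """A model assumption (e.g. equal engagement rates) is violated."""


class SingularModelError(BekinetError, ArithmeticError):
    """A degenerate rate combination makes outcome probabilities undefined."""


class RangeError(BekinetError, ValueError):
    """An energy argument lies outside the numerically supported range."""


class UnderdeterminedError(BekinetError, ValueError):
    """The data cannot identify the requested free parameters."""


class SchemaError(BekinetError, ValueError):
    """A tabular input file does not match the expected schema."""
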