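"""Exception hierarchy shared by all serpinkit modules."""


class SerpinkitError(Exception):
    """Base class for all serpinkit errors."""


class SchemaError(SerpinkitError):
    """A required column or config key is missing or malformed."""


class ValidationError(SerpinkitError):
    """Input data violates a structural invariant (bad times, negative
    concentrations, illegal residues, ...)."""


class InputError(SerpinkitError):
    """Not enough (or degenerate) data to run an operation."""


class DomainError(SerpinkitError):
    """A scalar argument is outside the mathematical domain of the
    operation (e.g. Km <= 0, control rate <= 0)."""


class DegenerateDataError(SerpinkitError):
    """Data carry no usable signal (all-constant trace, all-zero profile)."""


class NonInhibitoryError(SerpinkitError):
    """A titration shows no decreasing trend, so no stoichiometry exists."""
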