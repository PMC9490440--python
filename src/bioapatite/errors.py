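"""Exception hierarchy for the bioapatite pipeline."""


class BioapatiteError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(BioapatiteError):
    """A synthetic study design violates its invariants."""


class FormatError(BioapatiteError):
    """An input file does not match the documented schema."""


class EmptyInputError(FormatError):
    """An input file contains no data."""


class AnchorError(BioapatiteError):
    """A baseline anchor lies outside the spectrum range."""


class WindowError(BioapatiteError):
    """A feature-query window lies outside the spectrum range."""


class ConfigurationError(BioapatiteError):
    """A configuration value is unknown or inconsistent."""


class InsufficientDataError(BioapatiteError):
    """Too few rows/samples for the requested statistic."""


class DegenerateDesignError(BioapatiteError):
    """The predictor is constant; regression is undefined."""


class InsufficientClassError(BioapatiteError):
    """A class has too few samples for discriminant analysis."""


class SingularDesignError(BioapatiteError):
    """The within-group scatter matrix is singular; reduce features."""


class RuleInapplicableError(BioapatiteError):
    """A decision rule was invoked on a state it is not defined for."""


class IndeterminateInputError(BioapatiteError):
    """No usable evidence was supplied to a decision rule."""
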