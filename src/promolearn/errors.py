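"""Exception hierarchy for promoter-library processing."""


class PromolearnError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PromolearnError):
    """A configuration key is missing, malformed, or names an absent column."""


class AlphabetError(PromolearnError, ValueError):
    """A sequence contains a character outside {A, C, G, T}."""


class SequenceLengthError(PromolearnError, ValueError):
    """Sequences of unequal length, or a query of the wrong length."""


class DuplicateIdError(PromolearnError, ValueError):
    """Record identifiers collide."""


class ExpressionParseError(PromolearnError, ValueError):
    """An expression value could not be parsed as a number."""


class BinningError(PromolearnError, ValueError):
    """Quantile binning cannot produce the requested number of classes."""


class EmptyLibraryError(PromolearnError, ValueError):
    """An operation requires a nonempty library."""


class FeatureSelectionError(PromolearnError, ValueError):
    """Entropy filtering removed every position."""


class EstimatorError(PromolearnError, ValueError):
    """Unknown estimator kind or unsupported estimator operation."""


class SearchSpaceError(PromolearnError, ValueError):
    """Exhaustive design requested over an unenumerable sequence space."""
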