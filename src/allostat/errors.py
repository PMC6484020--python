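"""Exception hierarchy shared by all allostat modules."""


class AllostatError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(AllostatError):
    """A structure or trajectory file could not be parsed."""


class FormatError(AllostatError):
    """A file parsed but violates the format contract (e.g. frame atom-count mismatch)."""


class AnnotationError(AllostatError):
    """A required chain/region annotation is missing or inconsistent."""


class SelectionError(AllostatError):
    """An atom selection is empty, overlapping, or otherwise invalid."""


class EmptyInputError(AllostatError):
    """An operation received an ensemble or series with no usable frames."""


class SuperpositionError(AllostatError):
    """Rigid-body superposition is undefined for the given atom sets."""


class CorrespondenceError(AllostatError):
    """Atom selections in ensemble and reference cannot be put in 1:1 correspondence."""


class UndefinedCorrelationError(AllostatError):
    """Correlation requested on a series with zero variance."""


class BandwidthError(AllostatError):
    """Kernel bandwidth cannot be determined (degenerate sample)."""


class ScenarioError(AllostatError):
    """A synthetic-data scenario is internally inconsistent."""


class ValidationError(AllostatError):
    """Assay table or run configuration fails validation."""


class DegenerateWindowError(AllostatError):
    """Control signal does not exceed background; normalization undefined."""


class ComparisonError(AllostatError):
    """Two results are not comparable (substrate or complex mismatch)."""
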