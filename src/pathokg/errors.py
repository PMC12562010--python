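"""Exception hierarchy shared across the package."""


class PathoKGError(Exception):
    """Base class for all package errors."""


class VocabularyError(PathoKGError):
    """An edge type or node type outside the controlled vocabulary."""


class GraphError(PathoKGError):
    """Structural problem in a heterogeneous graph operation."""


class RangeError(PathoKGError, ValueError):
    """A numeric value outside its documented domain."""


class ParseError(PathoKGError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ReferenceAlleleError(PathoKGError):
    """A variant's reference allele disagrees with the chromosome sequence."""


class WindowError(PathoKGError, ValueError):
    """Infeasible context-window request (e.g. window longer than chromosome)."""


class TemplateError(PathoKGError):
    """A node-text template is missing a required field."""


class ConfigError(PathoKGError):
    """Invalid or incomplete run configuration."""


class ShapeError(PathoKGError, ValueError):
    """Array dimensions incompatible with the model architecture."""


class SplitError(PathoKGError):
    """A data split cannot be formed as requested."""
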