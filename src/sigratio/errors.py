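"""Exception hierarchy.

``ValidationError`` marks inputs that violate a documented precondition or
file-format contract; ``ComputationError`` marks inputs that are formally
valid but make the requested quantity undefined (zero-variance correlation,
empty tumor mask, non-positive untreated baseline).
"""


class SigratioError(Exception):
    """Base class for package errors."""


class ValidationError(SigratioError, ValueError):
    """Input violates a precondition or format contract."""


class FormatError(ValidationError):
    """Malformed input file (duplicate genes, non-numeric cells, bad columns)."""


class ComputationError(SigratioError, RuntimeError):
    """The requested quantity is undefined for this input."""
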