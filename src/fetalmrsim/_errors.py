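"""Exception hierarchy shared across the package.

Validation problems (bad user input, inconsistent metadata) are kept
distinct from geometry mismatches and from degenerate numerical inputs so
the command-line layer can map them onto exit codes.
"""


class FetalMRSimError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FetalMRSimError, ValueError):
    """Input violates a declared contract (unknown label, bad parameter)."""


class FormatError(FetalMRSimError):
    """A file exists but its payload is not what the format promises."""


class GeometryError(FetalMRSimError):
    """Two volumes that must share a grid do not."""


class DegenerateInputError(FetalMRSimError):
    """Structurally valid input on which the operation is meaningless
    (empty mask, zero variance)."""


class ParameterError(FetalMRSimError, ValueError):
    """A sequence/algorithm parameter combination is infeasible."""


class NamingError(FetalMRSimError):
    """Two outputs would collide on the same file name."""
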