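"""Exception hierarchy shared across the package."""


class MKMDError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(MKMDError):
    """Raised when a PDB text cannot yield an alpha-carbon chain."""


class DegenerateInputError(MKMDError):
    """Raised when an input is too small or too empty for the operation."""


class ConfigurationError(MKMDError):
    """Raised for unknown measure/centrality names or invalid settings."""


class ConstraintViolationError(MKMDError):
    """Raised when a kernel specification violates its simplex/bound constraints."""


class UndefinedMetricError(MKMDError):
    """Raised when a classification metric has a zero denominator."""


class SVMTrainingError(MKMDError):
    """Raised when the nu-SVM solver cannot produce a finite solution."""


class InfeasibleNuError(SVMTrainingError):
    """Raised when the nu regularizer is infeasible for the class balance."""
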