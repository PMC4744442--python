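"""Exception hierarchy.

Two broad classes matter for the CLI exit codes: input/validation problems
(exit 2) and numerical failures such as singular covariances (exit 3).
"""


class SdrGsaError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SdrGsaError, ValueError):
    """Malformed or contract-violating input (CLI exit code 2)."""


class ParseError(InvalidInputError):
    """A delimited/GMT file could not be parsed; message carries the location."""


class DegenerateSliceError(InvalidInputError):
    """A slice (phenotype level or quantile bin) has fewer than 2 samples."""


class ContractViolationError(InvalidInputError):
    """Slice moments fed to a statistic do not match its standardization mode."""


class ScenarioError(InvalidInputError):
    """A simulation scenario is internally inconsistent (e.g. non-PD covariance)."""


class NumericalError(SdrGsaError, ArithmeticError):
    """Numerical failure (CLI exit code 3)."""


class SingularMatrixError(NumericalError):
    """A matrix inverse square root was requested on a rank-deficient matrix."""
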