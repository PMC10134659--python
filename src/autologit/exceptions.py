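"""Package-specific exceptions."""


class AutologitError(Exception):
    """Base class for package errors."""


class ValidationError(AutologitError, ValueError):
    """Invalid input data or configuration (CLI exit code 2)."""


class SingularDesignError(ValidationError):
    """Design matrix is rank-deficient; message names the collinear columns."""


class ConvergenceError(AutologitError, RuntimeError):
    """Model fitting failed to converge (CLI exit code 3)."""
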