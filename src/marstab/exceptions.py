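"""Exception hierarchy.

Validation problems (bad shapes, infeasible designs, nonstationary
parameters where stationarity is required) are ``ValidationError``;
numerical failures during fitting are ``NumericalError``.
"""


class MarstabError(Exception):
    """Base class for all package errors."""


class ValidationError(MarstabError, ValueError):
    """Invalid input: shapes, ranges, masks, or preconditions."""


class DesignError(ValidationError):
    """Time-series design too small to estimate the requested model."""


class NonStationaryError(ValidationError):
    """Operation requires a stationary process but max |eigenvalue| >= 1."""

    def __init__(self, max_modulus: float):
        self.max_modulus = float(max_modulus)
        super().__init__(
            f"process is not stationary: max |eigenvalue of B| = "
            f"{self.max_modulus:.6g} >= 1"
        )


class NumericalError(MarstabError, RuntimeError):
    """Numerical failure (rank deficiency, non-convergence, ...)."""


class ConvergenceError(NumericalError):
    """Optimizer failed to converge; carries the best point found."""

    def __init__(self, message, best_params=None, diagnostics=None):
        super().__init__(message)
        self.best_params = best_params
        self.diagnostics = diagnostics or {}
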