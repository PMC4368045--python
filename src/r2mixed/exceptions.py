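"""Exception hierarchy for r2mixed."""


class R2MixedError(Exception):
    """Base class for all r2mixed errors."""


class InputError(R2MixedError, ValueError):
    """Invalid user input: missing columns, bad dimensions, empty data."""


class CovarianceError(R2MixedError, ValueError):
    """A random-effect covariance matrix failed validation."""


class DegenerateModelError(R2MixedError, RuntimeError):
    """The model carries no variance to partition (total variance is zero)."""


class ConvergenceError(R2MixedError, RuntimeError):
    """Optimizer failed to converge; carries the best state found so far."""

    def __init__(self, message, best_state=None):
        super().__init__(message)
        self.best_state = best_state
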