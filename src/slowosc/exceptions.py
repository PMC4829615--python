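"""Exception hierarchy used across the package."""


class SlowOscError(Exception):
    """Base class for package errors."""


class ValidationError(SlowOscError, ValueError):
    """Invalid input data (NaNs, wrong shapes, bad manifests)."""


class UnsupportedSamplingError(SlowOscError, ValueError):
    """The sampling rate cannot support the requested band scheme."""


class ParameterError(SlowOscError, ValueError):
    """A configuration parameter is outside its valid domain."""


class DegenerateSeriesError(SlowOscError, ArithmeticError):
    """A computation is undefined for this input (e.g. zero spectral mass)."""


class ConvergenceError(SlowOscError, RuntimeError):
    """An iterative algorithm failed to converge after annealing."""
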