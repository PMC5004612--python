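"""Exception hierarchy shared by all respiro modules."""


class RespiroError(ValueError):
    """Base class for all respiro-specific errors."""


class SamplingError(RespiroError):
    """Raised when a signal violates the uniform-sampling contract
    (non-uniform time column, mismatched sampling intervals, ...)."""


class DegenerateKernelError(RespiroError):
    """Raised when an impulse-response recording carries no usable signal
    (all zeros, or zero total area when normalization is requested)."""


class IllConditionedError(RespiroError):
    """Raised when an unregularized solve is requested on a system whose
    condition number exceeds the safety cap.  The remedy is to set a
    positive regularization weight gamma."""


class SingularSystemError(RespiroError):
    """Raised when the projected system HL is rank deficient and no ridge
    term was requested.  Two remedies exist: trim the transport-delay zeros
    from the kernel and the data (``eliminate_delay``), or solve with a
    positive gamma (``dr_solve_regularized``)."""


class ConstantSeriesError(RespiroError):
    """Raised when a correlation is requested between series that are
    constant on the evaluated region, where Pearson r is undefined."""
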