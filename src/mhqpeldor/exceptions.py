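"""Exception hierarchy for mhqpeldor."""


class MhqError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(MhqError):
    """Instrument geometry value is non-physical (zero or negative length)."""


class InvalidFlowError(MhqError):
    """Flow setting is non-physical (zero or negative rate / volume)."""


class OutOfModelError(MhqError):
    """Requested evaluation lies outside the validity domain of a model."""


class FitError(MhqError):
    """A least-squares fit failed to converge or is under-determined."""


class TraceError(MhqError):
    """A dipolar trace violates a structural requirement (grid, sign, units)."""


class ConditioningError(MhqError):
    """A linear system is too ill-conditioned to solve meaningfully."""
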