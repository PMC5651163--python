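"""Exception types shared across the package."""


class RpGrappaError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(RpGrappaError, ValueError):
    """A phantom / acquisition specification is degenerate or inconsistent."""


class GeometryError(RpGrappaError, ValueError):
    """A kernel geometry is incompatible with the data it is applied to."""


class ParameterError(RpGrappaError, ValueError):
    """An out-of-range algorithm parameter (e.g. reduction factor < 1)."""


class FormatError(RpGrappaError, ValueError):
    """A container file is missing a field or has inconsistent shapes."""


class NumericalFailure(RpGrappaError, RuntimeError):
    """An iterative solver produced non-finite iterates or diverged."""
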