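"""Exception types shared across the package."""


class CollagenMechError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(CollagenMechError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(CollagenMechError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. constant frame)."""


class UnreliableDetectionError(CollagenMechError, RuntimeError):
    """A detection ran but its result cannot be trusted (signal below noise floor)."""


class SolverError(CollagenMechError, RuntimeError):
    """A numerical solver failed to converge; carries diagnostics in the message."""
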