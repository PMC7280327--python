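"""Exception hierarchy shared across the package."""


class MyodecompError(Exception):
    """Base class for all package errors."""


class ValidationError(MyodecompError, ValueError):
    """Input violates a documented precondition or invariant."""


class NumericalError(MyodecompError, ArithmeticError):
    """A numerical procedure failed (singular system, rank deficiency...)."""


class StageError(MyodecompError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
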