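"""Exception hierarchy shared across the package."""


class PloidymlError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PloidymlError, ValueError):
    """An input falls outside its mathematical/physical domain."""


class DataError(PloidymlError, ValueError):
    """A dataset violates a structural contract (labels, balance, parsing)."""


class ConvergenceError(PloidymlError, RuntimeError):
    """An iterative solver failed to converge within its iteration cap."""


class StageError(PloidymlError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
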