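"""Exception types shared across the package."""


class PerturbgraphError(Exception):
    """Base class for package errors."""


class FormatError(PerturbgraphError, ValueError):
    """A file or table does not conform to the expected schema."""


class ValidationError(PerturbgraphError, ValueError):
    """An argument violates a documented precondition or invariant."""


class TrainingDivergedError(PerturbgraphError, RuntimeError):
    """Training aborted because a loss became non-finite."""

    def __init__(self, module: str, epoch: int):
        self.module = module
        self.epoch = epoch
        super().__init__(
            f"non-finite loss in module {module!r} at epoch {epoch}"
        )
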