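"""Exception hierarchy shared across the package."""


class FosnetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FosnetError, ValueError):
    """An input table does not conform to the documented schema."""


class GroupTooSmallError(FosnetError, ValueError):
    """A group has fewer subjects than the operation requires."""


class MissingBaselineError(FosnetError, ValueError):
    """A stratum lacks the baseline-age group needed for normalization."""


class PipelineStageError(FosnetError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
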