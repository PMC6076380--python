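"""Exception hierarchy shared across the pipeline."""


class MirProspectError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirProspectError, ValueError):
    """A configuration or argument value is invalid; the message names the field."""


class DataError(MirProspectError, ValueError):
    """Numerical contents of a matrix violate a precondition (e.g., non-positive value before log2)."""


class StructuralError(MirProspectError, ValueError):
    """Identifiers, shapes or file structure are inconsistent."""


class PipelineError(MirProspectError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause!r}")
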