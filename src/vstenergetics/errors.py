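"""Exception hierarchy shared across the pipeline."""


class VSTError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VSTError, ValueError):
    """A file does not conform to the canonical dialect (e.g. missing column)."""


class SessionValidationError(VSTError, ValueError):
    """Telemetry values violate a session invariant; message cites the row."""


class DomainError(VSTError, ValueError):
    """An input value is outside the mathematical domain of an operation."""


class ParameterError(VSTError, ValueError):
    """A configuration or tuning parameter is invalid."""


class AlignmentError(VSTError, ValueError):
    """Two per-sample sequences that must be aligned have different lengths."""


class AnalysisError(VSTError, RuntimeError):
    """An analysis stage cannot proceed (empty race set, missing T0, ...)."""


class DegenerateInputError(AnalysisError):
    """Statistical input has no usable variation (e.g. zero variance)."""


class StageError(VSTError, RuntimeError):
    """Pipeline failure wrapper carrying the stage name and subject id."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        self.stage = stage
        self.subject_id = subject_id
        self.cause = cause
        super().__init__(f"stage '{stage}' failed for subject '{subject_id}': {cause}")
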