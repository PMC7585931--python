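"""Exception hierarchy shared across the pipeline.

Every stage raises one of these so callers (and the CLI) can distinguish
malformed inputs from data that is formally valid but degenerate.
"""


class OispecError(Exception):
    """Base class for all package errors."""


class ValidationError(OispecError):
    """Input violates a structural precondition (shape, range, format)."""


class ConfigurationError(OispecError):
    """Inconsistent or impossible configuration (e.g. rank-deficient design)."""


class DegenerateDataError(OispecError):
    """Formally valid data that cannot support the requested computation
    (zero variance, empty ROI, no detected photons)."""


class StageError(OispecError):
    """Wraps a failure inside the session orchestrator with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
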