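"""Exception hierarchy shared across the package."""


class MSEPLSCError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MSEPLSCError, ValueError):
    """A record or table violates the data model (range, uniqueness, missing value)."""


class MontageError(MSEPLSCError, ValueError):
    """Channel set does not match the expected montage."""


class DegenerateSignalError(MSEPLSCError, ValueError):
    """A signal is unusable for entropy estimation (e.g. zero variance)."""


class DegenerateColumnError(MSEPLSCError, ValueError):
    """A column is constant within a group, so it cannot be normalized."""


class DegenerateRowError(MSEPLSCError, ValueError):
    """A salience row is constant, so its correlations are undefined."""


class AlignmentError(MSEPLSCError, ValueError):
    """Row/column alignment between two blocks is broken."""


class SubjectRejectedError(MSEPLSCError, ValueError):
    """A subject's features are unusable (undefined entropy at some scale)."""


class PipelineError(MSEPLSCError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending entity."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
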