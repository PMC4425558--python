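"""Exception hierarchy shared across the package."""


class PlscanError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(PlscanError, ValueError):
    """An operation received malformed arguments (wrong shape, length mismatch, ...)."""


class ConfigurationError(PlscanError, ValueError):
    """A spec object is invalid for the data it is applied to (e.g. Nyquist violations)."""


class DegenerateFitError(PlscanError, ValueError):
    """A distribution fit is not identifiable on the given data."""


class PipelineStageError(PlscanError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original!r}")
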