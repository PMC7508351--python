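"""Exception hierarchy shared across modules."""


class SymisleError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SymisleError):
    """Invalid simulation or pipeline configuration."""


class FormatError(SymisleError):
    """Malformed input file; message names the offending line."""


class NormalizationError(SymisleError):
    """Count matrix cannot be normalized (e.g. no gene covered in all samples)."""


class StageError(SymisleError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
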