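"""Exception hierarchy.

Every error raised by the package derives from :class:`FogBCIError`; the CLI
maps each subclass to a distinct nonzero exit code.
"""


class FogBCIError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(FogBCIError):
    """A parameter object or input value violates its invariants."""

    exit_code = 2


class ParseError(FogBCIError):
    """A data file could not be parsed into a valid record."""

    exit_code = 3


class ShapeError(FogBCIError):
    """An array has the wrong shape for the requested operation."""

    exit_code = 4


class DegenerateChannelError(FogBCIError):
    """A channel is constant and cannot be standardized."""

    exit_code = 5


class TooShortError(FogBCIError):
    """A record is too short for the requested filter."""

    exit_code = 6


class DegenerateLabelsError(FogBCIError):
    """A training set contains fewer than two classes."""

    exit_code = 7


class StratificationError(FogBCIError):
    """A stratified split cannot represent every class in both folds."""

    exit_code = 8


class DivergenceError(FogBCIError):
    """Autoencoder training produced a non-finite loss."""

    exit_code = 9

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")


class ConfigurationError(FogBCIError):
    """A model or pipeline configuration is internally inconsistent."""

    exit_code = 10


class TopologyError(FogBCIError):
    """The simulated network topology lacks a required node or link."""

    exit_code = 11


class StageError(FogBCIError):
    """A pipeline stage failed; carries the stage name."""

    exit_code = 12

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
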