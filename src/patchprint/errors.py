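"""Exception taxonomy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
StageError -> 4.
"""


class PatchprintError(Exception):
    """Base class for all package errors."""


class ConfigError(PatchprintError):
    """Invalid configuration (bad parameter combination, malformed config file)."""


class DataError(PatchprintError):
    """Invalid or unreadable input data (trace files, manifests)."""


class StageError(PatchprintError):
    """A pipeline stage failed on otherwise valid inputs."""


class ReducibleGeneratorError(StageError):
    """The gating scheme's generator matrix has no unique stationary distribution."""


class StateSeparationError(StageError):
    """Amplitude density is not bimodal: conducting and non-conducting states
    cannot be separated by a threshold current."""


class DegenerateFitError(StageError):
    """A curve fit is unidentifiable on the given points (e.g. constant open
    probability across potentials)."""


class TrainingDivergedError(StageError):
    """Autoencoder training produced a non-finite loss."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
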