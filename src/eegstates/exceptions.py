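"""Exception types raised across the package."""


class EegStatesError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(EegStatesError, ValueError):
    """An argument violates a documented precondition."""


class ChannelMismatchError(EegStatesError, ValueError):
    """Channel names in a recording do not match the montage."""


class SidecarError(EegStatesError, ValueError):
    """A matrix recording's JSON sidecar is missing or incomplete."""

class UndefinedCorrelationError(EegStatesError, ValueError):
    """Spatial correlation requested on a constant (zero-variance) map."""


class GenerationError(EegStatesError, RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""


class InsufficientDataError(EegStatesError, RuntimeError):
    """Not enough clean data remain to continue the analysis."""


class MissingArtifactError(EegStatesError, FileNotFoundError):
    """A pipeline stage requires an output that a prior stage never wrote."""
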