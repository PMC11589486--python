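"""Exception hierarchy for the oleohyst pipeline."""


class OleohystError(Exception):
    """Base class for all package errors."""


class ParameterError(OleohystError, ValueError):
    """A simulation or model parameter is out of its valid range."""


class ConfigError(OleohystError, ValueError):
    """A dataset configuration is inconsistent (e.g. duplicate cultivars)."""


class CapacityError(OleohystError, RuntimeError):
    """The image canvas cannot hold the requested number of fruits."""


class SegmentationError(OleohystError, RuntimeError):
    """No usable foreground remains after background removal."""


class JoinError(OleohystError, ValueError):
    """Color samples and oil records cannot be joined."""


class SelectionError(OleohystError, RuntimeError):
    """Predictor selection is impossible (e.g. every score undefined)."""


class RankDeficiencyError(OleohystError, ValueError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)
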