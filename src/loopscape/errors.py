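"""Exception hierarchy for loopscape."""


class LoopscapeError(Exception):
    """Base class for all loopscape errors."""


class StructureParseError(LoopscapeError):
    """A coordinate file could not be read or is syntactically invalid."""


class ConfigurationError(LoopscapeError):
    """Invalid configuration value (unknown format tag, bad region, ...)."""


class EmptySelectionError(LoopscapeError):
    """An atom selection resolved to zero atoms."""


class PairingError(LoopscapeError):
    """Two coordinate sets could not be paired (size mismatch etc.)."""


class FitError(LoopscapeError):
    """Rigid-body superposition is ill-posed (too few / degenerate points)."""


class RefinementError(FitError):
    """Outlier-rejecting refinement rejected too many pairs."""

    def __init__(self, message: str, cycle_trace=None):
        super().__init__(message)
        self.cycle_trace = list(cycle_trace or [])
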