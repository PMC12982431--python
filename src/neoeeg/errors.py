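"""Exception hierarchy."""


class NeoeegError(Exception):
    """Base class for all neoeeg errors."""


class FormatError(NeoeegError):
    """Unreadable or malformed input file."""


class MontageError(NeoeegError):
    """Required electrodes missing for the requested bipolar derivations."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing electrodes for montage: {', '.join(self.missing)}")


class PreprocessError(NeoeegError):
    """Preconditions for filtering/resampling not met."""


class CalibrationError(NeoeegError):
    """Not enough data to fit a novelty model or calibrate a threshold."""


class AggregationError(NeoeegError):
    """No channels left to aggregate over."""


class InsufficientDataError(NeoeegError):
    """No reliable segments remain; no estimate can be produced."""
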