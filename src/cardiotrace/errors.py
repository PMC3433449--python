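"""Exception hierarchy for trace analysis failures."""


class CardiotraceError(Exception):
    """Base class for all package errors."""


class TraceFormatError(CardiotraceError):
    """Malformed trace file: too few rows, unparseable numerics, bad columns."""


class SamplingError(CardiotraceError):
    """Sample times are not uniformly spaced within tolerance."""


class ParameterError(CardiotraceError):
    """Invalid generator or analysis parameter combination."""


class PlacementError(ParameterError):
    """An injected event violates its phase constraint."""


class ProtocolError(CardiotraceError):
    """Recording protocol violated (e.g. missing or misplaced caffeine puff)."""


class SignalQualityError(CardiotraceError):
    """Signal unusable, e.g. background-subtracted fluorescence non-positive."""


class AlignmentError(CardiotraceError):
    """Paired traces do not share a common time base."""


class TruncationError(CardiotraceError):
    """The quantity of interest runs off the end of the trace."""


class InsufficientDataError(CardiotraceError):
    """Too few beats/transients for the requested statistic."""

    def __init__(self, message: str, count: int | None = None):
        super().__init__(message)
        self.count = count


class ContractError(CardiotraceError):
    """Caller violated an operation precondition."""


class ConfigurationError(CardiotraceError):
    """Analysis configuration incompatible with the trace (e.g. dt too coarse)."""
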