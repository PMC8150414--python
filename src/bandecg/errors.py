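"""Exception hierarchy shared across the pipeline.

Every stage raises one of these so callers (and the CLI) can map failures
to exit codes without string matching.
"""


class BandEcgError(Exception):
    """Base class for all package errors."""


class TelemetryParseError(BandEcgError):
    """A telemetry CSV row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class ValidationError(BandEcgError):
    """Input data violates a container invariant (non-finite samples,
    decreasing timestamps, non-positive intervals, ...)."""


class ConfigurationError(BandEcgError):
    """A parameter is outside its legal range (cutoff above Nyquist,
    even smoothing window, negative tolerance, ...)."""


class InsufficientDataError(BandEcgError):
    """The input is structurally valid but too short for the operation."""


class UncorrectableSeriesError(BandEcgError):
    """RRI correction could not establish a sane local mean: every interval,
    including the series median, is abnormal."""


class AlignmentError(BandEcgError):
    """Two heart-rate series have no overlapping time span to pair on."""


class PipelineStageError(BandEcgError):
    """Wraps a stage failure with the stage name attached."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
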