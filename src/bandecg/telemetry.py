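"""Raw telemetry streams and their conversion to a uniform sampling grid.

A waistband ECG unit streams 16-bit ADC samples over Bluetooth at a nominal
125 samples/s, but the receiving phone logs *arrival* times, so the recorded
spacing is irregular: transport jitter shifts timestamps and packet loss
opens gaps.  The first pipeline stage therefore interpolates the stream onto
an exact uniform grid (1 kHz by default) before any filtering; beats lost in
long gaps are handled later, at the RR-interval level, not here.

All times in this package are milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import InsufficientDataError, TelemetryParseError, ValidationError

ADC_MIN, ADC_MAX = -32768, 32767


@dataclass
class TelemetryStream:
    """Irregularly-timed raw ADC samples as received over the wireless link.

    Attributes
    ----------
    times : np.ndarray
        Arrival timestamps in milliseconds, non-decreasing.  Fractional
        milliseconds are allowed.
    values : np.ndarray
        Integer ADC counts in the signed 16-bit range.
    nominal_rate : float
        The device's nominal sampling rate in samples/s (default 125).
    meta : dict
        Free-form provenance (source file, channel settings, ...).
    """

    times: np.ndarray
    values: np.ndarray
    nominal_rate: float = 125.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError("times and values must be 1-D and equal length")
        if self.nominal_rate <= 0:
            raise ValidationError("nominal_rate must be positive")
        if len(self.times) > 1 and np.any(np.diff(self.times) < 0):
            raise ValidationError("arrival timestamps must be non-decreasing")
        if len(self.values) and (
            self.values.min() < ADC_MIN or self.values.max() > ADC_MAX
        ):
            raise ValidationError("ADC values outside signed 16-bit range")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration_ms(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) > 1 else 0.0


@dataclass
class UniformSignal:
    """Evenly sampled real-valued signal with an explicit sampling rate.

    ``start_time`` anchors sample 0 on the same millisecond axis as the
    telemetry it came from, so beat times detected downstream are directly
    comparable to ground truth.
    """

    sampling_rate: float  # Hz
    start_time: float  # ms
    values: np.ndarray
    unit_label: str = "adc"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if len(self.values) and not np.all(np.isfinite(self.values)):
            raise ValidationError("signal contains non-finite samples")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Sample times in milliseconds."""
        step_ms = 1000.0 / self.sampling_rate
        return self.start_time + step_ms * np.arange(len(self.values))

    @property
    def duration_ms(self) -> float:
        return (len(self.values) - 1) * 1000.0 / self.sampling_rate if len(self) else 0.0


@dataclass
class CsvDialect:
    """Telemetry CSV layout: comma-separated, UTF-8, '.' decimal, columns
    (timestamp_ms, value), with an optional single header line."""

    separator: str = ","
    header: bool = True

    @property
    def header_line(self) -> str:
        return self.separator.join(("timestamp_ms", "value"))


def _looks_like_header(line: str, sep: str) -> bool:
    first = line.split(sep)[0].strip()
    try:
        float(first)
        return False
    except ValueError:
        return True


def read_telemetry_csv(
    path: str | Path,
    dialect: CsvDialect | None = None,
    nominal_rate: float = 125.0,
) -> TelemetryStream:
    """Read a telemetry stream from a two-column CSV file.

    One record per data row, in file order; a header line (detected by a
    non-numeric first field) is skipped.  Timestamps are parsed as
    milliseconds; values as integer ADC counts.

    Raises
    ------
    TelemetryParseError
        If a field is non-numeric, naming the 1-based line number.
    ValidationError
        If timestamps decrease.
    OSError
        If the file cannot be read.
    """
    dialect = dialect or CsvDialect()
    path = Path(path)
    times: list[float] = []
    values: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if lineno == 1 and _looks_like_header(line, dialect.separator):
                continue
            parts = line.split(dialect.separator)
            if len(parts) < 2:
                raise TelemetryParseError("expected 2 comma-separated fields", lineno)
            try:
                t = float(parts[0])
                v = int(round(float(parts[1])))
            except ValueError as exc:
                raise TelemetryParseError(f"non-numeric field ({exc})", lineno) from exc
            times.append(t)
            values.append(v)
    return TelemetryStream(
        np.array(times, dtype=float),
        np.array(values, dtype=np.int64),
        nominal_rate=nominal_rate,
        meta={"source": str(path)},
    )


def write_telemetry_csv(
    stream: TelemetryStream, path: str | Path, dialect: CsvDialect | None = None
) -> None:
    """Write a stream as two-column CSV; read → write → read is the identity."""
    dialect = dialect or CsvDialect()
    with open(path, "w", encoding="utf-8") as fh:
        if dialect.header:
            fh.write(dialect.header_line + "\n")
        for t, v in zip(stream.times, stream.values):
            # repr of a Python float keeps fractional-ms timestamps exact
            fh.write(f"{float(t)!r}{dialect.separator}{int(v)}\n")


def resample_uniform(
    stream: TelemetryStream,
    target_rate: float = 1000.0,
    kind: Literal["linear", "cubic"] = "linear",
) -> UniformSignal:
    """Interpolate an irregular telemetry stream onto a uniform grid.

    The grid spans [first, last] arrival time at exactly ``target_rate``;
    the interpolant passes through every input point and never extrapolates
    beyond the record span.  Duplicate timestamps keep the last value (a
    warning is emitted), matching Bluetooth batch arrivals.

    Parameters
    ----------
    target_rate : float
        Output sampling rate in Hz (default 1000, compensating the uneven
        received spacing before filtering).
    kind : {"linear", "cubic"}
        Linear is the default: exact on ramps and free of overshoot.
    """
    if len(stream) < 2:
        raise InsufficientDataError("resampling requires at least 2 records")
    t = stream.times
    v = stream.values.astype(float)
    if np.any(np.diff(t) == 0):
        warnings.warn("duplicate arrival timestamps: keeping the last value of each")
        # keep the LAST record of each equal-timestamp run
        keep = np.r_[np.diff(t) > 0, True]
        t, v = t[keep], v[keep]
    if len(t) < 2:
        raise InsufficientDataError("fewer than 2 distinct timestamps")

    step_ms = 1000.0 / target_rate
    n_out = int(np.floor((t[-1] - t[0]) / step_ms)) + 1
    grid = t[0] + step_ms * np.arange(n_out)
    # guard against float round-up past the last input time
    grid = grid[grid <= t[-1] + 1e-9]

    if kind == "linear":
        out = np.interp(grid, t, v)
    elif kind == "cubic":
        out = CubicSpline(t, v)(grid)
    else:
        raise ValidationError(f"unknown interpolation kind {kind!r}")
    return UniformSignal(
        sampling_rate=target_rate,
        start_time=float(t[0]),
        values=out,
        unit_label="adc",
    )
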