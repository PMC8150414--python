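"""RR intervals, lost-beat reconstruction, and heart-rate estimation.

From detected beats the pipeline computes RR intervals (RRI), repairs
abnormally long intervals caused by missed detections or dropped packets,
converts each interval to an instantaneous heart rate (HR = 60000 / RRI
bpm), and smooths the beat-to-beat series with a 5-point moving average.

The reconstruction treats an interval R as hiding lost beats when it
exceeds max(1500 ms, 1.5 × local mean RRI): the number of lost beats is
estimated from the local mean as k = round(R / local_mean), and R is
replaced by k equal sub-intervals summing to R exactly, so total recording
duration is conserved.  1500 ms is the printed exemplar of an out-of-range
beat interval; the relative clause keeps the rule meaningful at high heart
rates where even a shorter dropout spans several beats.

The magnitude of the smoothing problem: at a true rate of 72 bpm
(RRI = 833.33 ms) a single fiducial displaced by 50 ms changes the
one-interval HR by up to ≈4.6 bpm — hence the 5-beat average for the
reported rate.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    UncorrectableSeriesError,
    ValidationError,
)
from .qrs import BeatAnnotations


@dataclass
class RRISeries:
    """Inter-beat intervals in ms; ``end_times`` is the time of the later
    beat of each interval; ``corrected_mask`` flags reconstructed intervals."""

    end_times: np.ndarray
    intervals: np.ndarray
    corrected_mask: np.ndarray | None = None

    def __post_init__(self):
        self.end_times = np.asarray(self.end_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.corrected_mask is None:
            self.corrected_mask = np.zeros(len(self.intervals), dtype=bool)
        self.corrected_mask = np.asarray(self.corrected_mask, dtype=bool)
        if not (len(self.end_times) == len(self.intervals) == len(self.corrected_mask)):
            raise ValidationError("RRI field lengths differ")
        if len(self.intervals) and np.any(self.intervals <= 0):
            raise ValidationError("intervals must be strictly positive")
        if len(self.end_times) > 1 and np.any(np.diff(self.end_times) <= 0):
            raise ValidationError("end_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_duration_ms(self) -> float:
        return float(np.sum(self.intervals))


@dataclass
class HRSeries:
    """Beat-timed heart rates in bpm."""

    times: np.ndarray
    hr: np.ndarray
    smoothed: bool = False
    window: int = 1

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if len(self.times) != len(self.hr):
            raise ValidationError("times and hr lengths differ")
        if len(self.hr) and (np.any(~np.isfinite(self.hr)) or np.any(self.hr <= 0)):
            raise ValidationError("heart rates must be finite and positive")

    def __len__(self) -> int:
        return len(self.hr)


def default_correction_params() -> dict:
    return {
        "absolute_threshold_ms": 1500.0,
        "relative_factor": 1.5,
        "local_mean_memory": 8,
        "merge_short_intervals": False,   # false-detection removal, off by default
        "short_factor": 0.5,
    }


def compute_rri(beats: BeatAnnotations) -> RRISeries:
    """Successive differences of beat times: n beats give n − 1 intervals,
    each stamped with the time of its later beat."""
    t = beats.beat_times
    if len(t) < 2:
        raise InsufficientDataError("RRI needs at least 2 beats")
    return RRISeries(end_times=t[1:], intervals=np.diff(t))


def _is_abnormal(r: float, local_mean: float, p: dict) -> bool:
    return r > max(p["absolute_threshold_ms"], p["relative_factor"] * local_mean)


def correct_rri(rri: RRISeries, params: dict | None = None) -> RRISeries:
    """Reconstruct lost beats hidden in abnormally long intervals.

    An interval R is abnormal when it exceeds
    max(absolute_threshold, relative_factor × local mean); it is replaced by
    k = round(R / local_mean) equal sub-intervals (k ≥ 2, raised further if
    an equal split would itself still be abnormal) whose sum is exactly R.
    The local mean is the mean of the last 8 normal intervals, seeded by the
    series median.  Optionally, intervals shorter than half the local mean
    are merged into their successor (false-detection removal; off by
    default).

    Raises :class:`UncorrectableSeriesError` when no sane local mean exists
    (the series median is itself beyond the absolute threshold).
    """
    p = {**default_correction_params(), **(params or {})}
    if len(rri) == 0:
        return RRISeries(rri.end_times.copy(), rri.intervals.copy())
    median = float(np.median(rri.intervals))

    normals: deque[float] = deque(maxlen=int(p["local_mean_memory"]))
    out_ends: list[float] = []
    out_ivals: list[float] = []
    out_mask: list[bool] = []

    intervals = list(rri.intervals)
    ends = list(rri.end_times)

    if p["merge_short_intervals"]:
        merged_i: list[float] = []
        merged_e: list[float] = []
        i = 0
        while i < len(intervals):
            lm = float(np.mean(normals)) if normals else median
            if intervals[i] < p["short_factor"] * lm and i + 1 < len(intervals):
                merged_i.append(intervals[i] + intervals[i + 1])
                merged_e.append(ends[i + 1])
                i += 2
            else:
                if not _is_abnormal(intervals[i], lm, p):
                    normals.append(intervals[i])
                merged_i.append(intervals[i])
                merged_e.append(ends[i])
                i += 1
        intervals, ends = merged_i, merged_e
        normals.clear()

    for r, end in zip(intervals, ends):
        lm = float(np.mean(normals)) if normals else median
        if _is_abnormal(r, lm, p):
            if median > p["absolute_threshold_ms"] and not normals:
                raise UncorrectableSeriesError(
                    "series median is itself abnormal; no reference interval"
                )
            k = max(2, int(round(r / lm)))
            while _is_abnormal(r / k, lm, p):
                k += 1
            start = end - r
            sub_ends = start + r * np.arange(1, k + 1) / k
            sub_ends[-1] = end  # conserve total duration exactly
            prev = start
            for se in sub_ends:
                sub = se - prev
                out_ends.append(se)
                out_ivals.append(sub)
                out_mask.append(True)
                normals.append(sub)
                prev = se
        else:
            out_ends.append(end)
            out_ivals.append(r)
            out_mask.append(False)
            normals.append(r)

    return RRISeries(
        end_times=np.asarray(out_ends),
        intervals=np.asarray(out_ivals),
        corrected_mask=np.asarray(out_mask, dtype=bool),
    )


def hr_from_rri(rri: RRISeries) -> HRSeries:
    """Instantaneous heart rate: HR_i = 60000 / RRI_i bpm, stamped at the
    interval's end time."""
    if len(rri) and np.any(rri.intervals <= 0):
        raise ValidationError("intervals must be positive")
    return HRSeries(times=rri.end_times.copy(), hr=60000.0 / rri.intervals)


def smooth_hr(
    series: HRSeries,
    window: int = 5,
    mode: Literal["trailing", "centered"] = "trailing",
) -> HRSeries:
    """Moving-average smoothing of a beat-to-beat HR series.

    Default is the trailing 5-beat window (the reported rate at beat i is
    the mean of beats i−4…i); the first window−1 outputs average all
    available preceding points.  Output length equals input length.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigurationError("window must be odd and positive")
    hr = series.hr
    out = np.empty_like(hr)
    if mode == "trailing":
        csum = np.concatenate(([0.0], np.cumsum(hr)))
        for i in range(len(hr)):
            lo = max(0, i - window + 1)
            out[i] = (csum[i + 1] - csum[lo]) / (i + 1 - lo)
    elif mode == "centered":
        half = window // 2
        csum = np.concatenate(([0.0], np.cumsum(hr)))
        for i in range(len(hr)):
            lo, hi = max(0, i - half), min(len(hr), i + half + 1)
            out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    else:
        raise ConfigurationError(f"unknown smoothing mode {mode!r}")
    return HRSeries(times=series.times.copy(), hr=out, smoothed=True, window=window)
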