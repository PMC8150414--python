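"""Pan–Tompkins QRS detection.

A from-scratch implementation of the classic real-time detector: the
band-passed ECG is differentiated (5-point centred derivative), squared,
and integrated over a 150 ms moving window; candidate peaks of the
integrated waveform are then classified as QRS or noise by a pair of
adaptive running estimates (signal-peak level SPK, noise-peak level NPK)
with the threshold NPK + 0.25·(SPK − NPK).  A search-back pass rescans any
interval longer than 1.66× the running-average RR at half threshold, so an
occasional low-amplitude beat is still found; candidates arriving within
360 ms of the previous beat are rejected as T waves when their integrated
slope is less than half the previous beat's.  Accepted beats are finally
refined to the local absolute maximum of the band-passed signal within
±75 ms, which places the fiducial on the R wave of the input time axis.

All internal stages are zero-delay (centred kernels), so no group-delay
bookkeeping is needed.  Every constant lives in ``default_detector_params``
and is recorded in the annotation's ``detector_state``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, InsufficientDataError, ValidationError
from .telemetry import UniformSignal


@dataclass
class BeatAnnotations:
    """Strictly increasing QRS fiducial times (ms) with detection metadata."""

    beat_times: np.ndarray
    source: str = "detected"  # {detected, truth, corrected}
    detector_state: dict = field(default_factory=dict)

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if len(self.beat_times) > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValidationError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.beat_times)


@dataclass
class DetectionScore:
    """Beat-matching counts and the derived sensitivity / PPV."""

    true_positives: int
    false_positives: int
    false_negatives: int
    match_tolerance: float  # ms

    @property
    def sensitivity(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else float("nan")

    @property
    def positive_predictivity(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else float("nan")


def default_detector_params() -> dict:
    return {
        "derivative_points": 5,
        "integration_window_ms": 150.0,
        "refractory_ms": 200.0,
        "threshold_fraction": 0.25,       # THR = NPK + frac*(SPK-NPK)
        "peak_memory": 0.125,             # SPK/NPK <- mem*peak + (1-mem)*level
        "init_window_s": 2.0,
        "init_spk_fraction": 0.25,        # SPK0 = frac * max(integrated[:2 s])
        "init_npk_fraction": 0.5,         # NPK0 = frac * mean(integrated[:2 s])
        "searchback_rr_factor": 1.66,
        "searchback_rr_memory": 8,        # RRs averaged for the expected RR
        "searchback_peak_memory": 0.25,   # faster SPK update on search-back beats
        "twave_window_ms": 360.0,
        "twave_slope_fraction": 0.5,
        "refine_window_ms": 75.0,
    }


def _derivative(x: np.ndarray, fs: float) -> np.ndarray:
    """Centred 5-point derivative (zero delay)."""
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * fs / 8.0
    return np.convolve(np.pad(x, 2, mode="edge"), kernel, mode="valid")


def _integrate(x: np.ndarray, fs: float, window_ms: float) -> np.ndarray:
    n = max(3, int(round(window_ms * fs / 1000.0)))
    n += 1 - n % 2  # odd width -> centred window has zero delay
    kernel = np.full(n, 1.0 / n)
    return np.convolve(np.pad(x, n // 2, mode="edge"), kernel, mode="valid")


def _local_slope(integrated: np.ndarray, idx: int, half: int) -> float:
    lo, hi = max(0, idx - half), min(len(integrated), idx + half + 1)
    seg = np.diff(integrated[lo:hi])
    return float(np.max(seg)) if len(seg) else 0.0


def detect_qrs(
    sig: UniformSignal, params: dict | None = None
) -> BeatAnnotations:
    """Detect QRS complexes on a preprocessed (band-passed) signal.

    Returns beat times on the input's millisecond axis, strictly increasing
    and separated by at least the 200 ms refractory period.  An all-constant
    signal yields zero beats; a record shorter than 3 s raises
    :class:`InsufficientDataError`.
    """
    p = {**default_detector_params(), **(params or {})}
    fs = sig.sampling_rate
    if fs < 100:
        raise ConfigurationError("detection requires sampling rate >= 100 Hz")
    if sig.duration_ms < 3000:
        raise InsufficientDataError("detection requires at least 3 s of signal")

    x = sig.values - np.mean(sig.values)
    integ = _integrate(_derivative(x, fs) ** 2, fs, p["integration_window_ms"])
    if np.ptp(integ) == 0:  # flat signal: no beats, not an error
        return BeatAnnotations(np.array([]), source="detected",
                               detector_state={"params": p, "n_searchback": 0})

    refr = int(round(p["refractory_ms"] * fs / 1000.0))
    # -inf sentinels let a beat sitting on the record boundary qualify as a peak
    padded = np.concatenate(([-np.inf], integ, [-np.inf]))
    cand_idx, _ = sps.find_peaks(padded, distance=refr)
    cand_idx -= 1
    slope_half = int(round(p["integration_window_ms"] * fs / 2000.0))

    n_init = int(p["init_window_s"] * fs)
    spk = p["init_spk_fraction"] * float(np.max(integ[:n_init]))
    npk = p["init_npk_fraction"] * float(np.mean(integ[:n_init]))
    npk = min(npk, spk / 2.0)

    mem, sb_mem = p["peak_memory"], p["searchback_peak_memory"]
    beats: list[int] = []          # accepted indices on the integrated signal
    beat_slopes: list[float] = []
    rr_hist: list[float] = []
    rejected: list[int] = []       # sub-threshold candidates, for search-back
    n_searchback = 0

    def accept(idx: int, slope: float) -> None:
        beats.append(idx)
        beat_slopes.append(slope)
        if len(beats) > 1:
            rr_hist.append((beats[-1] - beats[-2]) / fs * 1000.0)

    for idx in cand_idx:
        peak = integ[idx]
        threshold = npk + p["threshold_fraction"] * (spk - npk)
        slope = _local_slope(integ, idx, slope_half)
        is_beat = peak > threshold
        if is_beat and beats:
            # T-wave discrimination inside the vulnerable window
            dt_ms = (idx - beats[-1]) / fs * 1000.0
            if dt_ms < p["twave_window_ms"] and slope < p["twave_slope_fraction"] * beat_slopes[-1]:
                is_beat = False
        if is_beat:
            # search-back over a too-long gap before committing this beat
            if rr_hist and beats:
                rr_avg = float(np.mean(rr_hist[-p["searchback_rr_memory"]:]))
                gap_ms = (idx - beats[-1]) / fs * 1000.0
                if gap_ms > p["searchback_rr_factor"] * rr_avg and rejected:
                    half_thr = threshold / 2.0
                    window = [
                        j for j in rejected
                        if beats[-1] + refr <= j <= idx - refr and integ[j] > half_thr
                    ]
                    if window:
                        best = max(window, key=lambda j: integ[j])
                        accept(best, _local_slope(integ, best, slope_half))
                        spk = sb_mem * integ[best] + (1 - sb_mem) * spk
                        n_searchback += 1
            accept(idx, slope)
            spk = mem * peak + (1 - mem) * spk
        else:
            rejected.append(idx)
            npk = mem * peak + (1 - mem) * npk

    beats.sort()

    # refine each fiducial to the local band-passed extremum of the record's
    # dominant R polarity (|x| alone can land on a deep S near boundaries)
    polarity = 1.0 if x[int(np.argmax(np.abs(x)))] >= 0 else -1.0
    refine = int(round(p["refine_window_ms"] * fs / 1000.0))
    refined: list[int] = []
    for idx in beats:
        lo, hi = max(0, idx - refine), min(len(x), idx + refine + 1)
        refined.append(lo + int(np.argmax(polarity * x[lo:hi])))

    # enforce the refractory period after refinement (keep the earlier beat)
    final: list[int] = []
    for idx in sorted(refined):
        if not final or idx - final[-1] >= refr:
            final.append(idx)

    step_ms = 1000.0 / fs
    times = sig.start_time + step_ms * np.asarray(final, dtype=float)
    state = {
        "params": p,
        "final_spk": spk,
        "final_npk": npk,
        "final_threshold": npk + p["threshold_fraction"] * (spk - npk),
        "n_searchback": n_searchback,
        "n_candidates": int(len(cand_idx)),
    }
    return BeatAnnotations(times, source="detected", detector_state=state)


def score_detection(
    detected: BeatAnnotations, truth: BeatAnnotations, tolerance: float = 20.0
) -> DetectionScore:
    """Score detected beats against ground truth by greedy one-to-one
    matching in time order within ±tolerance ms.

    Counts are consistent: TP + FN = |truth| and TP + FP = |detected|.
    """
    if tolerance < 0:
        raise ConfigurationError("tolerance must be non-negative")
    det = np.sort(np.asarray(detected.beat_times, dtype=float))
    tru = np.sort(np.asarray(truth.beat_times, dtype=float))
    i = j = tp = 0
    while i < len(det) and j < len(tru):
        diff = det[i] - tru[j]
        if abs(diff) <= tolerance:
            tp += 1
            i += 1
            j += 1
        elif diff < 0:
            i += 1
        else:
            j += 1
    return DetectionScore(
        true_positives=tp,
        false_positives=len(det) - tp,
        false_negatives=len(tru) - tp,
        match_tolerance=float(tolerance),
    )
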