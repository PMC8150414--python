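"""End-to-end orchestration of the heart-rate estimation pipeline.

Stage order: interpolate to a uniform grid → IIR high-pass (baseline)
→ FIR band-pass → Pan–Tompkins QRS detection → RR intervals → lost-beat
reconstruction → reciprocal heart rate → 5-point moving average.  All
intermediates are retained in the result; a run manifest (config digest,
package/library versions, per-stage timings) allows bit-identical re-runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError, InsufficientDataError, PipelineStageError
from .hr import (
    HRSeries,
    RRISeries,
    compute_rri,
    correct_rri,
    default_correction_params,
    hr_from_rri,
    smooth_hr,
)
from .preprocess import FilterSpec, bandpass_fir, remove_baseline
from .qrs import BeatAnnotations, default_detector_params, detect_qrs
from .telemetry import TelemetryStream, UniformSignal, resample_uniform

logger = logging.getLogger("bandecg.pipeline")

STAGE_ORDER = (
    "resample",
    "highpass",
    "bandpass",
    "detect",
    "rri",
    "correct",
    "hr",
    "smooth",
)


@dataclass
class PipelineConfig:
    """Full pipeline settings; the defaults reproduce the published chain
    (1 kHz interpolation, 0.5 Hz high-pass, 0.5–35 Hz order-30 band-pass,
    Pan–Tompkins detection, lost-beat correction, 5-point MAF)."""

    resample_rate: float = 1000.0
    interpolation: str = "linear"
    highpass: FilterSpec = field(
        default_factory=lambda: FilterSpec("iir_highpass", 0.5, order=2,
                                          design="butterworth")
    )
    bandpass: FilterSpec = field(
        default_factory=lambda: FilterSpec("fir_bandpass", 0.5, 35.0, order=30,
                                           design="hamming_sinc")
    )
    detector_params: dict = field(default_factory=default_detector_params)
    correction_params: dict = field(default_factory=default_correction_params)
    maf_window: int = 5
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if self.resample_rate <= 0:
            raise ConfigurationError("resample_rate must be positive")
        if self.maf_window < 1 or self.maf_window % 2 == 0:
            raise ConfigurationError("maf_window must be odd and positive")
        self.highpass.validate(self.resample_rate)
        self.bandpass.validate(self.resample_rate)

    def to_dict(self) -> dict:
        return {
            "resample_rate": self.resample_rate,
            "interpolation": self.interpolation,
            "highpass": {"cutoff_hz": self.highpass.cutoff_low,
                         "order": self.highpass.order},
            "bandpass": {"low_hz": self.bandpass.cutoff_low,
                         "high_hz": self.bandpass.cutoff_high,
                         "order": self.bandpass.order},
            "detector": self.detector_params,
            "correction": self.correction_params,
            "maf_window": self.maf_window,
            "seed": self.seed,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


_SCHEMA = {
    "resample_rate": (int, float),
    "interpolation": str,
    "highpass": dict,
    "bandpass": dict,
    "detector": dict,
    "correction": dict,
    "maf_window": int,
    "seed": int,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config with a schema-validation pass."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    for key, value in raw.items():
        if key not in _SCHEMA:
            raise ConfigurationError(f"unknown config key {key!r}")
        if not isinstance(value, _SCHEMA[key]):
            raise ConfigurationError(
                f"config key {key!r} must be {_SCHEMA[key]}, got {type(value)}"
            )
    cfg = PipelineConfig()
    if "resample_rate" in raw:
        cfg.resample_rate = float(raw["resample_rate"])
    if "interpolation" in raw:
        cfg.interpolation = raw["interpolation"]
    if "highpass" in raw:
        cfg.highpass = FilterSpec(
            "iir_highpass",
            cutoff_low=float(raw["highpass"].get("cutoff_hz", 0.5)),
            order=int(raw["highpass"].get("order", 2)),
            design="butterworth",
        )
    if "bandpass" in raw:
        cfg.bandpass = FilterSpec(
            "fir_bandpass",
            cutoff_low=float(raw["bandpass"].get("low_hz", 0.5)),
            cutoff_high=float(raw["bandpass"].get("high_hz", 35.0)),
            order=int(raw["bandpass"].get("order", 30)),
            design="hamming_sinc",
        )
    if "detector" in raw:
        cfg.detector_params = {**default_detector_params(), **raw["detector"]}
    if "correction" in raw:
        cfg.correction_params = {**default_correction_params(), **raw["correction"]}
    if "maf_window" in raw:
        cfg.maf_window = raw["maf_window"]
    if "seed" in raw:
        cfg.seed = raw["seed"]
    cfg.validate()
    return cfg


@dataclass
class PipelineResult:
    """All intermediates of one pipeline run plus its manifest."""

    uniform: UniformSignal
    filtered: UniformSignal
    beats: BeatAnnotations
    rri_raw: RRISeries
    rri_corrected: RRISeries
    hr_raw: HRSeries
    hr_smoothed: HRSeries
    manifest: dict


def run_pipeline(stream: TelemetryStream, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full chain on a telemetry stream.

    Requires at least 10 s of data.  Any stage failure is re-raised as
    :class:`PipelineStageError` with the stage name attached.
    """
    config = config or PipelineConfig()
    config.validate()
    if stream.duration_ms < 10_000:
        raise PipelineStageError(
            "resample", InsufficientDataError("pipeline requires >= 10 s of telemetry")
        )

    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "stage_order": list(STAGE_ORDER),
        "stages": {},
    }

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc
        elapsed = time.perf_counter() - t0
        n_out = len(out) if hasattr(out, "__len__") else None
        manifest["stages"][name] = {"seconds": round(elapsed, 4), "n_out": n_out}
        logger.info("stage %-8s n_out=%-8s %.3fs", name, n_out, elapsed)
        return out

    uniform = stage("resample", resample_uniform, stream,
                    config.resample_rate, config.interpolation)
    debased = stage("highpass", remove_baseline, uniform, config.highpass)
    filtered = stage("bandpass", bandpass_fir, debased, config.bandpass)
    beats = stage("detect", detect_qrs, filtered, config.detector_params)
    rri_raw = stage("rri", compute_rri, beats)
    rri_corr = stage("correct", correct_rri, rri_raw, config.correction_params)
    hr_raw = stage("hr", hr_from_rri, rri_corr)
    hr_smooth = stage("smooth", smooth_hr, hr_raw, config.maf_window)

    result = PipelineResult(uniform, filtered, beats, rri_raw, rri_corr,
                            hr_raw, hr_smooth, manifest)
    if config.output_dir:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_ms": result.uniform.times,
                  "value": result.uniform.values}).to_csv(
        out_dir / "uniform.csv", index=False)
    pd.DataFrame({"beat_time_ms": result.beats.beat_times}).to_csv(
        out_dir / "beats.csv", index=False)
    pd.DataFrame({"time_ms": result.rri_corrected.end_times,
                  "rri_ms": result.rri_corrected.intervals,
                  "corrected": result.rri_corrected.corrected_mask.astype(int)}
                 ).to_csv(out_dir / "rri.csv", index=False)
    pd.DataFrame({"time_ms": result.hr_smoothed.times,
                  "hr_bpm": result.hr_smoothed.hr}).to_csv(
        out_dir / "hr.csv", index=False)
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2)
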