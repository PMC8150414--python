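"""Device-agreement statistics for paired heart-rate series.

Quantifies how well the wearable's heart rate tracks a reference system:
mean error ± SD, MAE, MAPE, Bland–Altman 95% limits of agreement in both
difference (bpm) and ratio (device/reference) form, and the Pearson
correlation of the paired values.  Pairing is by linear interpolation of
both series onto a shared 1 s grid over their temporal overlap.

Sign convention: error = device − reference, stated in the report header.
MAPE denominators are the reference values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .errors import AlignmentError, InsufficientDataError, ValidationError
from .hr import HRSeries

LOA_MULTIPLIER = 1.96  # normal-approximation 95% limits


@dataclass
class PairedHR:
    """Time-aligned device/reference heart-rate pairs for one condition."""

    times: np.ndarray
    device_hr: np.ndarray
    reference_hr: np.ndarray
    condition_label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.device_hr = np.asarray(self.device_hr, dtype=float)
        self.reference_hr = np.asarray(self.reference_hr, dtype=float)
        if not (len(self.times) == len(self.device_hr) == len(self.reference_hr)):
            raise ValidationError("paired series lengths differ")
        for arr, name in ((self.device_hr, "device"), (self.reference_hr, "reference")):
            if len(arr) and (np.any(~np.isfinite(arr)) or np.any(arr <= 0)):
                raise ValidationError(f"{name} heart rates must be finite and positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class AgreementReport:
    """Agreement summary for one device/reference comparison.

    ``loa_lower/upper`` are the difference limits of agreement
    mean_error ± 1.96·sd_error (bpm); the ratio fields are the analogous
    statistics of device/reference.
    """

    n: int
    mean_device: float
    mean_reference: float
    mae: float
    mape: float
    mean_error: float
    sd_error: float
    loa_lower: float
    loa_upper: float
    ratio_mean: float
    ratio_loa_lower: float
    ratio_loa_upper: float
    pearson_r: float
    condition_label: str = ""
    error_convention: str = field(default="device - reference")

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    def to_text(self) -> str:
        lines = [
            f"Agreement report ({self.condition_label or 'unlabelled'}); "
            f"error = {self.error_convention}",
            f"  n pairs            : {self.n}",
            f"  mean HR device     : {self.mean_device:.2f} bpm",
            f"  mean HR reference  : {self.mean_reference:.2f} bpm",
            f"  MAE                : {self.mae:.2f} bpm",
            f"  MAPE               : {self.mape:.2f} %",
            f"  mean error (SD)    : {self.mean_error:.2f} ({self.sd_error:.2f}) bpm",
            f"  LoA (difference)   : {self.loa_lower:.2f} to {self.loa_upper:.2f} bpm",
            f"  ratio mean         : {self.ratio_mean:.4f}",
            f"  LoA (ratio)        : {self.ratio_loa_lower:.4f} to {self.ratio_loa_upper:.4f}",
            f"  Pearson r          : {self.pearson_r:.3f}",
        ]
        return "\n".join(lines)


def align_hr(
    device: HRSeries,
    reference: HRSeries,
    grid_step: float = 1.0,
    condition_label: str = "",
) -> PairedHR:
    """Pair two HR series by linear interpolation onto a shared grid.

    ``grid_step`` is in seconds (default 1 s).  Both series are
    interpolated over the intersection of their time spans; anything
    outside the overlap is discarded.
    """
    if len(device) < 2 or len(reference) < 2:
        raise InsufficientDataError("each series needs at least 2 points")
    start = max(device.times[0], reference.times[0])
    end = min(device.times[-1], reference.times[-1])
    if end <= start:
        raise AlignmentError("series have no overlapping time span")
    step_ms = grid_step * 1000.0
    if end - start < 2 * step_ms:
        raise InsufficientDataError("overlap shorter than two grid steps")
    n = int(np.floor((end - start) / step_ms)) + 1
    grid = start + step_ms * np.arange(n)
    dev = np.interp(grid, device.times, device.hr)
    ref = np.interp(grid, reference.times, reference.hr)
    return PairedHR(grid, dev, ref, condition_label=condition_label)


def agreement_stats(pairs: PairedHR) -> AgreementReport:
    """Compute the full agreement summary for a paired comparison.

    error_i = device_i − reference_i; MAE = mean|error|;
    MAPE = 100·mean(|error_i|/reference_i); SDs use the n−1 denominator;
    LoA = mean ± 1.96·SD for both the differences and the ratios
    device_i/reference_i.  Pearson r is computed on the raw pairs and is
    NaN when either side is constant.
    """
    if len(pairs) < 2:
        raise InsufficientDataError("agreement needs at least 2 pairs")
    dev, ref = pairs.device_hr, pairs.reference_hr
    if np.any(ref <= 0):
        raise ValidationError("reference heart rates must be positive")
    err = dev - ref
    ratio = dev / ref
    sd_err = float(np.std(err, ddof=1))
    sd_ratio = float(np.std(ratio, ddof=1))
    if np.std(dev) == 0 or np.std(ref) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(dev, ref)[0, 1])
    mean_err = float(np.mean(err))
    mean_ratio = float(np.mean(ratio))
    return AgreementReport(
        n=len(pairs),
        mean_device=float(np.mean(dev)),
        mean_reference=float(np.mean(ref)),
        mae=float(np.mean(np.abs(err))),
        mape=float(100.0 * np.mean(np.abs(err) / ref)),
        mean_error=mean_err,
        sd_error=sd_err,
        loa_lower=mean_err - LOA_MULTIPLIER * sd_err,
        loa_upper=mean_err + LOA_MULTIPLIER * sd_err,
        ratio_mean=mean_ratio,
        ratio_loa_lower=mean_ratio - LOA_MULTIPLIER * sd_ratio,
        ratio_loa_upper=mean_ratio + LOA_MULTIPLIER * sd_ratio,
        pearson_r=r,
        condition_label=pairs.condition_label,
    )


def bland_altman_plot(pairs: PairedHR, path: str) -> None:
    """Write Bland–Altman (difference vs mean) and correlation scatter
    panels to an image file.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = agreement_stats(pairs)
    mean_pair = (pairs.device_hr + pairs.reference_hr) / 2.0
    diff = pairs.device_hr - pairs.reference_hr
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.scatter(mean_pair, diff, s=8, alpha=0.6)
    for y, style in ((rep.mean_error, "-"), (rep.loa_lower, "--"), (rep.loa_upper, "--")):
        ax1.axhline(y, linestyle=style, color="k", linewidth=0.8)
    ax1.set_xlabel("mean HR (bpm)")
    ax1.set_ylabel("device − reference (bpm)")
    ax1.set_title("Bland–Altman")
    ax2.scatter(pairs.reference_hr, pairs.device_hr, s=8, alpha=0.6)
    lims = [min(pairs.reference_hr.min(), pairs.device_hr.min()),
            max(pairs.reference_hr.max(), pairs.device_hr.max())]
    ax2.plot(lims, lims, "k--", linewidth=0.8)
    ax2.set_xlabel("reference HR (bpm)")
    ax2.set_ylabel("device HR (bpm)")
    ax2.set_title(f"r = {rep.pearson_r:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
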