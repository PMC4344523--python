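"""Quantitative-FISH intensity-to-length calibration from plasmid standards.

Slides seeded with plasmid vectors carrying 135 (810 bp) or 270 (1620 bp)
telomere-sequence repeat inserts are processed in parallel with the samples;
the mean integrated probe intensity of the 810-bp standard fixes both the
intensity-per-bp slope (zero intercept — background is subtracted upstream)
and the minimum detection threshold applied to ECTR calling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import foci as _foci
from .preprocess import estimate_background
from .stack import ImageStack

#: Insert sizes of the packaged standards, bp of telomere sequence.
STANDARD_810_BP = 810.0
STANDARD_1620_BP = 1620.0

MIN_STANDARD_FOCI = 10


class CalibrationError(ValueError):
    """Raised for unusable calibration inputs or an unfitted model."""


@dataclass
class StandardStats:
    bp: float
    n_foci: int
    mean_intensity: float
    sd_intensity: float


@dataclass
class ChannelCalibration:
    """Per-channel slope, threshold and diagnostics."""

    channel: str
    slope_intensity_per_bp: float
    min_threshold_intensity: float
    standard_stats: list[StandardStats] = field(default_factory=list)
    noise_sigma: float | None = None
    linearity_residual: float | None = None  # relative residual of the 1620 std


@dataclass
class CalibrationModel:
    """Calibrations for the telomere probe channels (TelC, TelG)."""

    channels: dict[str, ChannelCalibration] = field(default_factory=dict)

    def slope(self, channel: str) -> float:
        try:
            return self.channels[channel].slope_intensity_per_bp
        except KeyError:
            raise CalibrationError(f"no calibration for channel {channel!r}")

    def min_threshold(self, channel: str) -> float | None:
        """Minimum-intensity threshold, or None for uncalibrated channels."""
        cc = self.channels.get(channel)
        return None if cc is None else cc.min_threshold_intensity

    def noise_sigma(self, channel: str) -> float:
        cc = self.channels.get(channel)
        if cc is None or cc.noise_sigma is None:
            raise CalibrationError(f"noise_sigma not estimated for {channel!r}")
        return cc.noise_sigma

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            name: {
                "channel": cc.channel,
                "slope_intensity_per_bp": cc.slope_intensity_per_bp,
                "min_threshold_intensity": cc.min_threshold_intensity,
                "noise_sigma": cc.noise_sigma,
                "linearity_residual": cc.linearity_residual,
                "standard_stats": [vars(s) for s in cc.standard_stats],
            }
            for name, cc in self.channels.items()
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        channels = {}
        for name, cd in d.items():
            stats = [StandardStats(**s) for s in cd.pop("standard_stats", [])]
            channels[name] = ChannelCalibration(standard_stats=stats, **cd)
        return cls(channels=channels)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_calibration(
    intensities_810,
    intensities_1620=None,
    channel: str = "TelG",
    noise_sigma: float | None = None,
) -> ChannelCalibration:
    """Fit a zero-intercept intensity-per-bp calibration for one channel.

    With only the 810-bp standard, slope = mean(I_810) / 810.  With both
    standards, the slope is the least-squares line through the origin on the
    (bp, mean intensity) pairs, and the relative residual of the 1620-bp
    standard is reported as a linearity diagnostic.  The minimum detection
    threshold is always the mean intensity of the 810-bp standard.
    """
    i810 = np.asarray(intensities_810, dtype=float)
    if i810.size < MIN_STANDARD_FOCI:
        raise CalibrationError(
            f"need >= {MIN_STANDARD_FOCI} foci for the 810-bp standard, "
            f"got {i810.size}"
        )
    mean810 = float(i810.mean())
    stats = [
        StandardStats(STANDARD_810_BP, int(i810.size), mean810, float(i810.std()))
    ]
    residual = None
    if intensities_1620 is None:
        slope = mean810 / STANDARD_810_BP
    else:
        i1620 = np.asarray(intensities_1620, dtype=float)
        if i1620.size < MIN_STANDARD_FOCI:
            raise CalibrationError(
                f"need >= {MIN_STANDARD_FOCI} foci for the 1620-bp standard, "
                f"got {i1620.size}"
            )
        mean1620 = float(i1620.mean())
        stats.append(
            StandardStats(
                STANDARD_1620_BP, int(i1620.size), mean1620, float(i1620.std())
            )
        )
        bp = np.array([STANDARD_810_BP, STANDARD_1620_BP])
        means = np.array([mean810, mean1620])
        slope = float(np.sum(bp * means) / np.sum(bp * bp))
        residual = float((mean1620 - slope * STANDARD_1620_BP)
                         / (slope * STANDARD_1620_BP))
    if not (slope > 0 and math.isfinite(slope)):
        raise CalibrationError("fitted slope must be positive")
    return ChannelCalibration(
        channel=channel,
        slope_intensity_per_bp=slope,
        min_threshold_intensity=mean810,
        standard_stats=stats,
        noise_sigma=noise_sigma,
        linearity_residual=residual,
    )


def intensity_to_bp(intensity, model: CalibrationModel, channel: str):
    """Convert background-corrected integrated intensity to base pairs."""
    slope = model.slope(channel)
    bp = np.asarray(intensity, dtype=float) / slope
    bp = np.clip(bp, 0.0, None)
    return float(bp) if np.isscalar(intensity) else bp


def detection_limit_bp(model: CalibrationModel, snr: float, channel: str) -> float:
    """Smallest length whose expected intensity reaches ``snr`` x noise sigma.

    This is informational: the operating cut remains the 810-bp-standard
    threshold, which by construction sits above this limit for any tolerable
    signal-to-noise ratio.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    return snr * model.noise_sigma(channel) / model.slope(channel)


def estimate_noise_sigma(
    stack: ImageStack,
    channel: str,
    background=None,
    mask: np.ndarray | None = None,
    n_apertures: int = 200,
    params: "_foci.DetectionParams | None" = None,
    seed=0,
) -> float:
    """Focus-scale background noise: robust SD of integrated intensity over
    randomly placed, focus-sized null apertures.

    Apertures use the same Mahalanobis-ellipsoid shape as focus measurement.
    ``mask`` restricts candidate centers (e.g. to the Halo); the robust
    (MAD-based) SD keeps the occasional aperture that lands on a real focus
    from inflating the estimate.
    """
    params = params or _foci.DetectionParams()
    rng = np.random.default_rng(seed)
    img = stack.channel(channel).astype(np.float64)
    if background is None:
        background = estimate_background(stack, channel)
    sig = img - background.as_field()
    sigma_vox = tuple(
        s / v for s, v in zip(params.log_sigma_um, stack.voxel_size_um)
    )
    offsets = _foci._aperture_offsets(sigma_vox, params.aperture_sigma)
    ext = np.abs(offsets).max(axis=0)
    shape = np.asarray(sig.shape)
    lo, hi = ext, shape - ext - 1
    if np.any(hi <= lo):
        raise CalibrationError("stack too small for null apertures")
    sums = []
    attempts = 0
    while len(sums) < n_apertures and attempts < 50 * n_apertures:
        attempts += 1
        c = np.array([rng.integers(l, h + 1) for l, h in zip(lo, hi)])
        if mask is not None and not mask[tuple(c)]:
            continue
        vox = c[None, :] + offsets
        sums.append(float(sig[vox[:, 0], vox[:, 1], vox[:, 2]].sum()))
    if len(sums) < max(20, n_apertures // 4):
        raise CalibrationError("could not place enough null apertures")
    sums = np.asarray(sums)
    mad = np.median(np.abs(sums - np.median(sums)))
    return float(1.4826 * mad)
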