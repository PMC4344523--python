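"""End-to-end analysis pipeline: stacks in, per-focus/per-nucleus tables out.

One nucleus at a time: Richardson–Lucy deconvolution -> DAPI core/Halo
segmentation -> per-channel LoG focus detection -> calibration threshold and
length estimation -> per-nucleus metrics.  After all nuclei, centromere-count
cell-cycle bins are assigned against the modal 2N count and group summaries
are written.  Per-nucleus failures are recorded and skipped; the run fails
only if every nucleus fails.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    CalibrationModel,
    estimate_noise_sigma,
    fit_calibration,
)
from .foci import DetectionParams, apply_detection_threshold, detect_foci
from .io import parameter_hash, read_stack, write_stack
from .preprocess import PSFModel, deconvolve, estimate_background
from .quantify import (
    NucleusMetrics,
    assign_cell_cycle_bin,
    group_summary,
    metrics_to_dataframe,
    summarize_nucleus,
)
from .segmentation import SegmentationParams, segment_nuclear_core
from .simdata import SimConfig, simulate_calibration_slide
from .stack import FOCUS_CHANNELS, ImageStack

logger = logging.getLogger(__name__)

_TEL_CHANNELS = ("TelC", "TelG")


@dataclass(frozen=True)
class PipelineParams:
    """Analysis-stage parameters (everything after acquisition)."""

    psf: PSFModel = field(default_factory=PSFModel)
    deconvolution_iterations: int = 10
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    coloc_max_distance_um: float = 0.3
    modal_2n_count: int | None = None  # default: mode of observed counts
    # centromere foci have no bp calibration; they pass if their integrated
    # intensity exceeds this multiple of the per-stack null-aperture noise
    cen_min_snr: float = 3.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunConfig:
    """Run-level configuration for the CLI pipeline."""

    input_dir: str
    out_dir: str
    calibration_json: str | None = None
    std810_dir: str | None = None
    std1620_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        params_d = d.pop("params", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        params = _params_from_dict(params_d)
        return cls(params=params, **d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _params_from_dict(d: dict) -> PipelineParams:
    d = dict(d)
    kwargs = {}
    sub = {
        "psf": PSFModel,
        "segmentation": SegmentationParams,
        "detection": DetectionParams,
    }
    for key, typ in sub.items():
        if key in d:
            block = d.pop(key)
            fields = {f.name for f in dataclasses.fields(typ)}
            unknown = set(block) - fields
            if unknown:
                raise ValueError(f"unknown keys in params.{key}: {sorted(unknown)}")
            block = {
                k: tuple(v) if isinstance(v, list) else v for k, v in block.items()
            }
            kwargs[key] = typ(**block)
    fields = {f.name for f in dataclasses.fields(PipelineParams)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown keys in params: {sorted(unknown)}")
    kwargs.update(d)
    return PipelineParams(**kwargs)


# ---------------------------------------------------------------------------
# calibration from slides
# ---------------------------------------------------------------------------


def measure_standard_slide(
    stack: ImageStack,
    params: PipelineParams,
    channels=_TEL_CHANNELS,
    min_snr: float = 2.0,
) -> dict[str, np.ndarray]:
    """Detect calibration foci and return per-channel intensity arrays.

    Detections dimmer than ``min_snr`` times the null-aperture noise are
    discarded: a standards slide contains only bright plasmid foci, so
    sub-noise detections are spurious and would drag the standard mean down.
    """
    dec = deconvolve(stack, params.psf, params.deconvolution_iterations,
                     channels=channels)
    out = {}
    for channel in channels:
        bg = estimate_background(stack, channel)
        noise = estimate_noise_sigma(stack, channel, bg, params=params.detection)
        foci = detect_foci(stack, channel, None, params.detection, bg,
                           deconvolved=dec)
        out[channel] = np.array(
            [
                f.integrated_intensity
                for f in foci
                if not f.border_clipped
                and f.integrated_intensity >= max(min_snr * noise, 0.5)
            ]
        )
    return out


def calibrate_from_slides(
    stack810: ImageStack,
    stack1620: ImageStack | None = None,
    params: PipelineParams | None = None,
    fit_both_standards: bool = False,
) -> CalibrationModel:
    """Fit per-channel calibrations from standard-slide stacks.

    By default the slope is fitted on the 810-bp standard alone (the 1620-bp
    standard, when given, supplies the linearity diagnostic), matching the
    assay's use of the 135-repeat standard as the operating reference.
    Set ``fit_both_standards`` to fit the zero-intercept line on both.
    """
    params = params or PipelineParams()
    i810 = measure_standard_slide(stack810, params)
    i1620 = (
        measure_standard_slide(stack1620, params)
        if stack1620 is not None
        else {c: None for c in _TEL_CHANNELS}
    )
    model = CalibrationModel()
    for channel in _TEL_CHANNELS:
        noise = estimate_noise_sigma(stack810, channel, params=params.detection)
        cc = fit_calibration(
            i810[channel],
            i1620[channel] if fit_both_standards else None,
            channel=channel,
            noise_sigma=noise,
        )
        if not fit_both_standards and i1620[channel] is not None:
            mean1620 = float(np.mean(i1620[channel]))
            cc.linearity_residual = float(
                (mean1620 - cc.slope_intensity_per_bp * 1620.0)
                / (cc.slope_intensity_per_bp * 1620.0)
            )
        model.channels[channel] = cc
    return model


def simulate_and_calibrate(
    config: SimConfig,
    params: PipelineParams | None = None,
    n_foci: int = 120,
    seed=0,
) -> CalibrationModel:
    """Simulate both standard slides under ``config`` and fit the calibration."""
    rng = np.random.default_rng(seed)
    s810, _ = simulate_calibration_slide(135, n_foci, config, seed=rng)
    s1620, _ = simulate_calibration_slide(270, n_foci, config, seed=rng)
    return calibrate_from_slides(s810, s1620, params)


# ---------------------------------------------------------------------------
# per-nucleus analysis
# ---------------------------------------------------------------------------


def analyze_stack(
    stack: ImageStack,
    calibration: CalibrationModel,
    params: PipelineParams | None = None,
    nucleus_id: str = "",
) -> tuple[NucleusMetrics, dict[str, list]]:
    """Run the full single-nucleus pipeline on one stack."""
    params = params or PipelineParams()
    dec = deconvolve(stack, params.psf, params.deconvolution_iterations,
                     channels=FOCUS_CHANNELS)
    compartments = segment_nuclear_core(stack, params.segmentation)
    foci_by_channel: dict[str, list] = {}
    for channel in FOCUS_CHANNELS:
        if not stack.has_channel(channel):
            continue
        bg = estimate_background(stack, channel)
        foci = detect_foci(
            stack, channel, compartments, params.detection, bg, nucleus_id,
            deconvolved=dec,
        )
        uncal_floor = None
        if calibration.min_threshold(channel) is None:
            noise = estimate_noise_sigma(
                stack, channel, bg, mask=compartments.halo_mask,
                params=params.detection,
            )
            uncal_floor = params.cen_min_snr * noise
        apply_detection_threshold(foci, calibration, uncal_floor)
        foci_by_channel[channel] = foci
    metrics = summarize_nucleus(
        compartments,
        foci_by_channel,
        calibration,
        nucleus_id=nucleus_id,
        coloc_max_distance_um=params.coloc_max_distance_um,
        modal_2n_count=None,
    )
    return metrics, foci_by_channel


def assign_cell_cycle_bins(
    metrics_list: list[NucleusMetrics],
    modal_2n_count: int | None = None,
) -> int | None:
    """Assign G1/S/G2 bins in place; returns the modal 2N count used.

    With no explicit modal count, the mode of the observed core centromere
    counts is used (ties resolved toward the smaller count, since G1 is the
    most populated phase of an asynchronous culture).
    """
    counts = [m.centromere_count_core for m in metrics_list
              if m.centromere_count_core > 0]
    if modal_2n_count is None:
        if not counts:
            return None
        freq = Counter(counts)
        top = max(freq.values())
        modal_2n_count = min(c for c, n in freq.items() if n == top)
    for m in metrics_list:
        if m.centromere_count_core > 0:
            m.cell_cycle_bin = assign_cell_cycle_bin(
                m.centromere_count_core, modal_2n_count
            )
    return modal_2n_count


def _foci_rows(foci_by_channel: dict, nucleus_id: str, run_hash: str):
    for channel, foci in foci_by_channel.items():
        for f in foci:
            yield {
                "run_hash": run_hash,
                "nucleus_id": nucleus_id,
                "channel": channel,
                "z_um": f.centroid_um[0],
                "y_um": f.centroid_um[1],
                "x_um": f.centroid_um[2],
                "voxel_count": f.voxel_count,
                "integrated_intensity": f.integrated_intensity,
                "compartment": f.compartment,
                "estimated_bp": f.estimated_bp,
                "passes_threshold": f.passes_threshold,
                "border_clipped": f.border_clipped,
            }


def run_pipeline(config: RunConfig) -> dict:
    """Analyze every stack in ``config.input_dir``; write tables and a report.

    Returns the JSON-able run report.  Raises ``RuntimeError`` if no stack
    could be analyzed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    in_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(in_dir.glob("*.tif")) + sorted(in_dir.glob("*.tiff"))
    if not paths:
        raise RuntimeError(f"no TIFF stacks found in {in_dir}")

    params = config.params
    if config.calibration_json:
        calibration = CalibrationModel.from_json(config.calibration_json)
    elif config.std810_dir:
        s810 = _read_first_stack(config.std810_dir)
        s1620 = (
            _read_first_stack(config.std1620_dir) if config.std1620_dir else None
        )
        calibration = calibrate_from_slides(s810, s1620, params)
    else:
        raise RuntimeError("no calibration source configured")

    # provenance hash covers the analysis parameters, not I/O paths, so the
    # same analysis of the same data hashes identically wherever it is run
    run_hash = parameter_hash({"params": params.to_dict(),
                               "seed": config.seed})
    metrics_list: list[NucleusMetrics] = []
    focus_rows: list[dict] = []
    errors: dict[str, str] = {}
    for path in paths:
        nucleus_id = path.stem
        try:
            stack = read_stack(path)
            metrics, foci_by_channel = analyze_stack(
                stack, calibration, params, nucleus_id
            )
        except Exception as exc:  # per-nucleus fault isolation
            logger.error("nucleus %s failed: %s", nucleus_id, exc)
            errors[nucleus_id] = str(exc)
            continue
        metrics_list.append(metrics)
        focus_rows.extend(_foci_rows(foci_by_channel, nucleus_id, run_hash))

    if not metrics_list:
        raise RuntimeError("all nuclei failed; see log")

    modal = assign_cell_cycle_bins(metrics_list, params.modal_2n_count)

    metrics_df = metrics_to_dataframe(metrics_list)
    metrics_df.insert(0, "run_hash", run_hash)
    focus_df = pd.DataFrame(focus_rows)
    metrics_df.to_csv(out_dir / "per_nucleus.csv", index=False,
                      float_format="%.6g")
    focus_df.to_csv(out_dir / "per_focus.csv", index=False, float_format="%.6g")

    metrics_df["group"] = "all"
    summary = group_summary(metrics_df, by="group")
    summary.insert(0, "run_hash", run_hash)
    summary.to_csv(out_dir / "group_summary.csv", index=False,
                   float_format="%.6g")

    report = {
        "halofish_version": __version__,
        "run_hash": run_hash,
        "seed": config.seed,
        "n_nuclei_analyzed": len(metrics_list),
        "n_nuclei_failed": len(errors),
        "errors": errors,
        "modal_2n_count": modal,
        "calibration": calibration.to_dict(),
        "config": config.to_dict(),
    }
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def _read_first_stack(directory) -> ImageStack:
    paths = sorted(Path(directory).glob("*.tif")) + sorted(
        Path(directory).glob("*.tiff")
    )
    if not paths:
        raise RuntimeError(f"no TIFF stacks found in {directory}")
    return read_stack(paths[0], require_channels=_TEL_CHANNELS)
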