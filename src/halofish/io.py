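"""OME-TIFF, ground-truth and configuration I/O."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .stack import CHANNELS, ChannelMissingError, ImageStack
from .simdata import GroundTruth

logger = logging.getLogger(__name__)

DEFAULT_VOXEL_SIZE_UM = (0.2, 0.16, 0.16)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as OME-TIFF with channel names and voxel-size metadata."""
    dz, dy, dx = stack.voxel_size_um
    data = stack.voxels.astype(np.float32)
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
            "SignificantBits": stack.bit_depth,
        },
    )


def read_stack(
    path,
    channel_names: tuple[str, ...] | None = None,
    require_channels: tuple[str, ...] = CHANNELS,
) -> ImageStack:
    """Read an OME-TIFF into an :class:`ImageStack`.

    Channel names and voxel sizes come from the OME metadata; either can be
    overridden (``channel_names``) or fall back to package defaults with a
    warning when missing.  Raises :class:`ChannelMissingError` if any channel
    in ``require_channels`` is absent.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        ome = tf.ome_metadata

    if data.ndim == 3:
        data = data[None, ...]
        axes = "C" + axes if "C" not in axes else axes
    if data.ndim != 4:
        raise ValueError(f"expected a CZYX stack, got axes {axes!r}")
    # normalize axis order to CZYX
    axes = axes.replace("S", "C")
    order = [axes.index(a) for a in "CZYX"]
    data = np.transpose(data, order)

    voxel = list(DEFAULT_VOXEL_SIZE_UM)
    names: list[str] | None = None
    bit_depth = 12
    if ome:
        try:
            meta = tifffile.xml2dict(ome)["OME"]["Image"]
            if isinstance(meta, list):
                meta = meta[0]
            px = meta["Pixels"]
            voxel = [
                float(px.get("PhysicalSizeZ", voxel[0])),
                float(px.get("PhysicalSizeY", voxel[1])),
                float(px.get("PhysicalSizeX", voxel[2])),
            ]
            ch = px.get("Channel", [])
            if isinstance(ch, dict):
                ch = [ch]
            got = [c.get("Name") for c in ch]
            if all(g is not None for g in got) and len(got) == data.shape[0]:
                names = [str(g) for g in got]
            bit_depth = int(px.get("SignificantBits", bit_depth))
        except (KeyError, TypeError, ValueError):
            warnings.warn(f"{path.name}: unparseable OME metadata; using defaults")
    else:
        warnings.warn(f"{path.name}: no OME metadata; using default voxel size")

    if channel_names is not None:
        names = list(channel_names)
    if names is None:
        names = list(CHANNELS[: data.shape[0]])
    if len(names) != data.shape[0]:
        raise ValueError("channel_names length does not match data")
    missing = [c for c in require_channels if c not in names]
    if missing:
        raise ChannelMissingError(
            f"{path.name}: missing required channel(s) {missing}"
        )
    return ImageStack(
        voxels=data.astype(np.float32),
        voxel_size_um=tuple(voxel),
        bit_depth=bit_depth,
        channel_names=tuple(names),
    )


def write_ground_truth(truths: list[GroundTruth], json_path, csv_path=None) -> None:
    """Ground truth as JSON (one record per nucleus) and flat per-molecule CSV."""
    with open(json_path, "w") as fh:
        json.dump([t.to_dict() for t in truths], fh, indent=1)
    if csv_path is not None:
        import pandas as pd

        rows = []
        for t in truths:
            for m in t.molecules:
                rows.append(
                    {
                        "nucleus_id": t.nucleus_id,
                        "strand": m.strand,
                        "repeat_length_bp": m.repeat_length_bp,
                        "z_um": m.position_um[0],
                        "y_um": m.position_um[1],
                        "x_um": m.position_um[2],
                        "compartment_truth": m.compartment_truth,
                        "cell_cycle_truth": t.cell_cycle_truth,
                    }
                )
        pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.6g")


def read_ground_truth(json_path) -> list[GroundTruth]:
    with open(json_path) as fh:
        return [GroundTruth.from_dict(d) for d in json.load(fh)]


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def parameter_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance columns."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
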