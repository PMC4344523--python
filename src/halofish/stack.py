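"""In-memory container for a multi-channel 3D acquisition.

One :class:`ImageStack` holds the four-channel z-stack acquired for a single
deproteinized nucleus (or for a calibration slide field): DAPI counterstain,
pan-centromere probe (CEN), C-strand telomere probe (TelC) and G-strand
telomere probe (TelG), with the physical voxel spacing attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical channel order used throughout the package.
CHANNELS: tuple[str, ...] = ("DAPI", "CEN", "TelC", "TelG")

#: Channels on which focus detection runs (DAPI is segmentation-only).
FOCUS_CHANNELS: tuple[str, ...] = ("CEN", "TelC", "TelG")

#: Telomere-strand probe channels, keyed by strand letter.
STRAND_CHANNELS: dict[str, str] = {"G": "TelG", "C": "TelC"}


class ChannelMissingError(KeyError):
    """Raised when a required channel is absent from a stack."""


@dataclass
class ImageStack:
    """A channel x z x y x x voxel grid in camera units (ADU).

    Parameters
    ----------
    voxels:
        Array of shape ``(C, Z, Y, X)``; non-negative intensities.
    voxel_size_um:
        Physical spacing ``(z, y, x)`` in micrometres.
    bit_depth:
        Camera bit depth the data were quantized to (8, 12 or 16).
    channel_names:
        One name per channel; must be unique.
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    bit_depth: int = 12
    channel_names: tuple[str, ...] = field(default=CHANNELS)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must have shape (C, Z, Y, X)")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError("channel_names length must match channel axis")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel spacing must be positive")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(Z, Y, X)`` array for one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ChannelMissingError(
                f"channel {name!r} not in stack (has {self.channel_names})"
            ) from None
        return self.voxels[idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names

    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size_um
        return dz * dy * dx
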