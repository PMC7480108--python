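"""Calibrated image container.

All stages of the package exchange :class:`ImageScene` objects: a raster
with a fixed five-dimensional axis order ``(C, T, Z, Y, X)`` plus the
physical calibration needed to convert pixels to micrometres and frames
to minutes.  Axes that are absent in the acquisition have size 1.

Conventions
-----------
* pixel indices are 0-based, origin at the top-left corner, y increases
  downward (raster convention);
* physical units are micrometres and minutes throughout the package;
  conversions happen at I/O time only;
* angles are reported in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageScene"]


@dataclass
class ImageScene:
    """A calibrated multi-channel, multi-frame, multi-z raster.

    Parameters
    ----------
    data
        Intensity array of shape ``(C, T, Z, Y, X)``.  Arrays with fewer
        dimensions are promoted by prepending singleton axes.
    pixel_size
        Lateral pixel size in µm/pixel.
    frame_interval
        Time between frames in minutes (ignored when T == 1).
    z_step
        Axial spacing in µm (ignored when Z == 1).
    channel_names
        Optional labels, one per channel.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float = 1.0
    z_step: float = 1.0
    channel_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim > 5:
            raise ValueError(f"at most 5 axes (C,T,Z,Y,X) supported, got {arr.ndim}")
        while arr.ndim < 5:
            arr = arr[np.newaxis]
        self.data = arr
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if arr.min() < 0:
            raise ValueError("intensities must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_frames > 1 and self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 for a time series")
        if self.n_z > 1 and self.z_step <= 0:
            raise ValueError("z_step must be > 0 for a z-stack")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.n_channels))
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal number of channels")

    # -- axis helpers -----------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_z(self) -> int:
        return self.data.shape[2]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    def plane(self, channel: int = 0, frame: int = 0, z: int = 0) -> np.ndarray:
        """Return one 2D (Y, X) plane."""
        return self.data[channel, frame, z]

    def channel_index(self, name_or_index: int | str) -> int:
        """Resolve a channel given by name or integer index."""
        if isinstance(name_or_index, (int, np.integer)):
            idx = int(name_or_index)
            if not 0 <= idx < self.n_channels:
                raise IndexError(f"channel index {idx} out of range")
            return idx
        try:
            return self.channel_names.index(name_or_index)
        except ValueError:
            raise KeyError(
                f"channel {name_or_index!r} not in {self.channel_names}"
            ) from None

    def to_um(self, pixels: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(pixels) * self.pixel_size
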