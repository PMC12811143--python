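"""Calibrated multi-channel image volumes.

Axis convention used throughout the package: arrays are (C, Z, Y, X) with
Z = anterior->posterior, Y = base->apex, and X increasing toward the
anatomical *left*. Profile positions are given in micrometres with 0 at
the X midline of the volume, so negative positions are anatomically right
and positive positions are anatomically left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXIS_CONVENTION = (
    "CZYX; Z anterior->posterior, Y base->apex, X right->left; "
    "positions in um with 0 at the X midline"
)


@dataclass
class MultiChannelVolume:
    """A voxel stack with physical calibration and named channels.

    Parameters
    ----------
    data
        Array of shape (C, Z, Y, X).
    voxel_size_um
        Physical size of one voxel along (Z, Y, X), micrometres.
    channel_names
        One unique name per channel.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel_names: tuple[str, ...]
    axis_convention: str = field(default=AXIS_CONVENTION)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected (C, Z, Y, X) array, got ndim={self.data.ndim}")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be 3 positive floats (Z, Y, X)")
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one channel name per channel required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as a (Z, Y, X) array."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(f"unknown channel {name_or_index!r}") from None
        else:
            idx = int(name_or_index)
        return self.data[idx]

    def x_positions_um(self) -> np.ndarray:
        """Micrometre position of each X column, 0 at the volume midline."""
        nx = self.data.shape[3]
        return (np.arange(nx) - (nx - 1) / 2.0) * self.voxel_size_um[2]
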