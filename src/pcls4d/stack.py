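"""In-memory containers for image data.

``Stack4D`` always carries five axes ``(t, c, z, y, x)`` (singletons
allowed), physical voxel sizes in µm and the frame interval in seconds.
``LabelVolume`` is a non-negative integer instance mask over ``(z, y, x)``
with 0 as background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_CHANNELS = ("membrane", "cytoplasm", "nuclei")


@dataclass
class Stack4D:
    data: np.ndarray                                  # (t, c, z, y, x)
    voxel_size: tuple[float, float, float]            # (dz, dy, dx) µm
    frame_interval: float = 1.0                       # s
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"Stack4D requires 5 axes (t,c,z,y,x); got {self.data.ndim}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")
        if len(self.channel_names) != self.data.shape[1]:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[1]))

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def channel(self, name_or_index) -> np.ndarray:
        """All frames of one channel, shape (t, z, y, x)."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(f"unknown channel {name_or_index!r}; "
                               f"have {self.channel_names}") from None
        else:
            idx = int(name_or_index)
        return self.data[:, idx]


@dataclass
class LabelVolume:
    labels: np.ndarray                                # (z, y, x) int
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume requires 3 axes (z, y, x)")
        if np.issubdtype(self.labels.dtype, np.floating):
            raise ValueError("labels must be integer")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def relabel_contiguous(self) -> "LabelVolume":
        """Map the label set onto 1..K preserving order."""
        vals = np.unique(self.labels)
        vals = vals[vals != 0]
        lut = np.zeros(self.labels.max() + 1 if self.labels.size else 1, dtype=self.labels.dtype)
        lut[vals] = np.arange(1, len(vals) + 1)
        return LabelVolume(lut[self.labels], self.voxel_size)
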