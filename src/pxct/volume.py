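"""The pipeline's central container: a 3D scalar grid with voxel metadata."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

CHANNELS = ("label", "delta", "electron_density", "mass_density")


@dataclass
class Volume3D:
    """A 3D scalar volume (axes ordered z, y, x) with isotropic voxel size.

    ``channel`` names the physical quantity stored per voxel: integer phase
    labels, the refractive-index decrement delta, electron density (e/A^3),
    or mass density (g/cm^3).
    """

    grid: np.ndarray
    channel: str
    voxel_size_nm: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional (z, y, x)")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.voxel_size_nm <= 0:
            raise ValueError("voxel size must be positive")
        if self.channel == "label":
            if not np.issubdtype(self.grid.dtype, np.integer):
                raise ValueError("label channel requires an integer grid")
            if self.grid.min() < 0:
                raise ValueError("labels must be non-negative")
        elif not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def with_grid(self, grid: np.ndarray, channel: str | None = None) -> "Volume3D":
        return replace(self, grid=grid, channel=channel or self.channel)

    def copy(self) -> "Volume3D":
        return replace(self, grid=self.grid.copy())
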