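"""Voxel-grid container shared by simulation and segmentation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass
class VoxelGrid:
    """A 3D intensity stack with anisotropic voxel spacing.

    Parameters
    ----------
    values
        Non-negative intensity array, axis order ``(z, y, x)``.
    spacing
        Voxel spacing in micrometres per axis, ``(z, y, x)``.

    Coordinates are 0-based; voxel ``i`` along an axis with spacing ``s``
    occupies the half-open interval ``[i*s, (i+1)*s)`` and its centre is at
    ``(i + 0.5) * s``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3:
            raise ValueError("spacing must have one entry per axis (z, y, x)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in μm³."""
        return float(np.prod(self.spacing))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the grid per axis in μm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical centre coordinates of every voxel along ``axis`` (μm)."""
        return (np.arange(self.shape[axis]) + 0.5) * self.spacing[axis]
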