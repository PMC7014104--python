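"""Axis-aligned scalar density grids.

A :class:`DensityGrid` holds a bulk-normalized probe density field: the value
in each voxel is a dimensionless multiple of the bulk probe density, so 1.0
means "same as bulk solvent" and an isovalue of 12 means "twelve times bulk".
The grid is defined by an origin (corner of the first voxel), a per-axis
spacing and the voxel counts; voxel centers sit at
``origin + (index + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridError

__all__ = ["DensityGrid"]


@dataclass
class DensityGrid:
    """3D scalar field of bulk-normalized probe density.

    Parameters
    ----------
    origin:
        Cartesian coordinates (Å) of the corner of voxel (0, 0, 0).
    spacing:
        Voxel edge length per axis (Å); a scalar is broadcast to all axes.
    values:
        Array of shape ``(nx, ny, nz)`` with non-negative densities in
        multiples of bulk density.
    probe:
        Probe-molecule label (e.g. ``IPA``, ``ACN``, ``PYR``).
    n_frames:
        Number of trajectory frames averaged into the grid.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    probe: str = ""
    n_frames: int = 0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        spacing = np.asarray(self.spacing, dtype=float)
        if spacing.ndim == 0:
            spacing = np.repeat(spacing, 3)
        self.spacing = spacing.reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GridError(f"grid values must be 3D, got shape {self.values.shape}")
        if np.any(self.spacing <= 0):
            raise GridError(f"grid spacing must be positive, got {self.spacing}")
        if min(self.values.shape) < 1:
            raise GridError("grid must have at least one voxel per axis")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in Å³."""
        return float(np.prod(self.spacing))

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Cartesian centers (Å) for an ``(n, 3)`` array of voxel indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + (idx + 0.5) * self.spacing

    def edges(self) -> list[np.ndarray]:
        """Bin edges per axis, suitable for ``np.histogramdd``."""
        return [
            self.origin[a] + self.spacing[a] * np.arange(self.dims[a] + 1)
            for a in range(3)
        ]

    def congruent_with(self, other: "DensityGrid", atol: float = 1e-6) -> bool:
        """True if two grids share origin, spacing and dims (superposable voxelwise)."""
        return (
            self.dims == other.dims
            and bool(np.allclose(self.origin, other.origin, atol=atol))
            and bool(np.allclose(self.spacing, other.spacing, atol=atol))
        )
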