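"""Shared voxel-grid container.

All maps, masks and series in the pipeline live on one co-registered,
atlas-like grid (default 1 mm isotropic). :class:`VolumeGrid` carries the
array together with its voxel spacing so that volumes in mm^3 are always
computed consistently; 4D arrays (DSC dynamics, Z-spectrum offsets) use the
last axis for the non-spatial dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass
class VolumeGrid:
    """A scalar field on a regular 3D grid (optionally with a 4th axis).

    Parameters
    ----------
    data : ndarray
        3D array, or 4D with the trailing axis holding dynamics/offsets.
    spacing : tuple of float
        Voxel edge lengths in mm along the three spatial axes.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected a 3D or 4D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VolumeGrid") -> bool:
        return self.shape3d == other.shape3d and np.allclose(self.spacing, other.spacing)

    def require_same_grid(self, other: "VolumeGrid") -> None:
        if not self.same_grid(other):
            a = self.name or "volume A"
            b = other.name or "volume B"
            raise GridMismatchError(
                f"grid mismatch between {a!r} (shape {self.shape3d}, spacing {self.spacing}) "
                f"and {b!r} (shape {other.shape3d}, spacing {other.spacing})"
            )


def as_array(vol) -> np.ndarray:
    """Accept a VolumeGrid or a bare ndarray and return the ndarray."""
    return vol.data if isinstance(vol, VolumeGrid) else np.asarray(vol)
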