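"""Image-volume and ROI-mask containers shared by all stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    intensities
        3D array of voxel values.
    voxel_spacing
        Physical edge length of a voxel along each axis, in mm. Anisotropic
        spacing (e.g. 0.6 x 0.6 x 5.0 mm) is fully supported.
    origin
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    intensities: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite intensities")
        spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"voxel_spacing must be 3 positive floats, got {self.voxel_spacing}")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "voxel_spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers for an (n, 3) index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.voxel_spacing) + np.asarray(self.origin)


@dataclass(frozen=True)
class RoiMask:
    """Binary region-of-interest mask on the grid of its companion volume."""

    support: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.support).astype(bool)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        if not arr.any():
            raise ValueError("mask is empty: at least one voxel must be set")
        object.__setattr__(self, "support", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.support.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.support.sum())

    def check_grid(self, volume: ImageVolume) -> None:
        if self.support.shape != volume.shape:
            raise ValueError(
                f"mask shape {self.support.shape} does not match volume shape {volume.shape}"
            )
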