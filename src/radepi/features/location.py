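"""Tumor-location features relative to the anterior-commissure landmark.

Six features describe where the ROI centroid sits relative to a reference
point (the AC in real anatomy, the grid center in phantoms): the spherical
polar coordinates (r, theta, phi) of the displacement and its city-block,
Chebyshev and Euclidean distances. r and the Euclidean distance coincide by
definition; both are kept because the feature inventory lists both.

Conventions: theta is measured from the +z (superior) axis in [0, pi];
phi is the azimuth of (dx, dy) from +x, in (-pi, pi]. At zero displacement
all six features are 0 by documented convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from radepi.volume import ImageVolume, RoiMask


@dataclass(frozen=True)
class LocationFeatures:
    r: float
    theta: float
    phi: float
    city_block: float
    chebyshev: float
    euclidean: float

    def as_dict(self) -> dict[str, float]:
        return {
            "r": self.r,
            "theta": self.theta,
            "phi": self.phi,
            "city_block": self.city_block,
            "chebyshev": self.chebyshev,
            "euclidean": self.euclidean,
        }


def compute_centroid(mask: RoiMask, volume: ImageVolume, study_id: str = "<study>") -> np.ndarray:
    """Unweighted mean of ROI voxel centers in physical (mm) coordinates."""
    mask.check_grid(volume)
    idx = np.argwhere(mask.support)
    if idx.size == 0:
        raise ValueError(f"empty ROI mask for study {study_id}")
    centers = volume.voxel_centers_mm(idx)
    return centers.mean(axis=0)


def extract_location_features(centroid_mm: np.ndarray, ac_mm: np.ndarray) -> LocationFeatures:
    """Distances and polar coordinates of the centroid relative to the AC."""
    centroid_mm = np.asarray(centroid_mm, dtype=float)
    ac_mm = np.asarray(ac_mm, dtype=float)
    if not (np.all(np.isfinite(centroid_mm)) and np.all(np.isfinite(ac_mm))):
        raise ValueError("centroid and AC coordinates must be finite")
    d = centroid_mm - ac_mm
    euclidean = float(np.sqrt(np.sum(d * d)))
    city_block = float(np.sum(np.abs(d)))
    chebyshev = float(np.max(np.abs(d)))
    if euclidean == 0.0:
        return LocationFeatures(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    theta = float(np.arccos(np.clip(d[2] / euclidean, -1.0, 1.0)))
    phi = float(np.arctan2(d[1], d[0])) if (d[0] != 0.0 or d[1] != 0.0) else 0.0
    return LocationFeatures(euclidean, theta, phi, city_block, chebyshev, euclidean)
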