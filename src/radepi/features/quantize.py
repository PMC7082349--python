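"""Gray-level quantization of within-ROI intensities.

All texture matrices operate on integer levels ``1..n_levels`` produced by
equal-width binning of the within-ROI intensity range. A constant ROI maps
entirely to level 1. Quantization is recomputed per image (original and each
wavelet sub-band), which makes every texture feature invariant to adding a
constant to all intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from radepi.volume import ImageVolume, RoiMask


@dataclass(frozen=True)
class QuantizationConfig:
    """Equal-width gray-level binning over the within-ROI min..max range."""

    n_levels: int = 32

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError(f"n_levels must be >= 2, got {self.n_levels}")


def quantize_intensities(
    volume: ImageVolume | np.ndarray,
    mask: RoiMask,
    q: QuantizationConfig = QuantizationConfig(),
) -> np.ndarray:
    """Map within-ROI intensities to integer levels 1..n_levels.

    Returns an int array of the volume's shape with 0 outside the ROI and
    levels in ``1..q.n_levels`` inside. Bin ``k`` covers
    ``[min + (k-1)*w, min + k*w)`` with ``w = (max - min)/n_levels``; the
    maximum maps to the top level. A constant ROI maps wholly to level 1.
    """
    arr = volume.intensities if isinstance(volume, ImageVolume) else np.asarray(volume, dtype=float)
    if arr.shape != mask.shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume shape {arr.shape}")
    inside = mask.support
    values = arr[inside]
    lo, hi = float(values.min()), float(values.max())
    levels = np.zeros(arr.shape, dtype=np.int64)
    if hi == lo:
        levels[inside] = 1
        return levels
    width = (hi - lo) / q.n_levels
    binned = np.floor((values - lo) / width).astype(np.int64) + 1
    np.clip(binned, 1, q.n_levels, out=binned)
    levels[inside] = binned
    return levels
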