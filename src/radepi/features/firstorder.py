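"""First-order statistics (FOS) over within-ROI intensities.

Seventeen features describe the intensity distribution inside the ROI.
Entropy and uniformity are computed on the quantized gray-level histogram
(same equal-width binning as the texture matrices); everything else is
computed on raw intensities. Dispersion features of a constant or
single-voxel ROI are 0 by convention, never an error.
"""

from __future__ import annotations

import numpy as np

from radepi.features.quantize import QuantizationConfig, quantize_intensities
from radepi.volume import ImageVolume, RoiMask

FOS_NAMES: tuple[str, ...] = (
    "energy",
    "entropy",
    "kurtosis",
    "skewness",
    "mean",
    "median",
    "maximum",
    "minimum",
    "range",
    "mean_absolute_deviation",
    "root_mean_square",
    "standard_deviation",
    "variance",
    "uniformity",
    "percentile_10",
    "percentile_90",
    "interquartile_range",
)


def extract_fos(
    volume: ImageVolume | np.ndarray,
    mask: RoiMask,
    q: QuantizationConfig = QuantizationConfig(),
) -> dict[str, float]:
    """The 17 first-order features over within-ROI intensities."""
    arr = volume.intensities if isinstance(volume, ImageVolume) else np.asarray(volume, dtype=float)
    x = arr[mask.support]

    mean = float(x.mean())
    var = float(x.var())  # population variance (ddof=0)
    std = float(np.sqrt(var))
    centered = x - mean
    if std > 0:
        skewness = float(np.mean(centered**3) / std**3)
        kurtosis = float(np.mean(centered**4) / std**4 - 3.0)  # excess kurtosis
    else:
        skewness = 0.0
        kurtosis = 0.0

    levels = quantize_intensities(arr, mask, q)[mask.support]
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / x.size
    entropy = float(-np.sum(p * np.log2(p)))
    uniformity = float(np.sum(p * p))

    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    return {
        "energy": float(np.sum(x * x)),
        "entropy": entropy,
        "kurtosis": kurtosis,
        "skewness": skewness,
        "mean": mean,
        "median": float(np.median(x)),
        "maximum": float(x.max()),
        "minimum": float(x.min()),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.mean(np.abs(centered))),
        "root_mean_square": float(np.sqrt(np.mean(x * x))),
        "standard_deviation": std,
        "variance": var,
        "uniformity": uniformity,
        "percentile_10": float(p10),
        "percentile_90": float(p90),
        "interquartile_range": float(p75 - p25),
    }
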