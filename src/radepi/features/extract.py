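"""Full 734-feature extraction for one volume + mask + AC triple."""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from radepi.features.firstorder import extract_fos
from radepi.features.location import compute_centroid, extract_location_features
from radepi.features.matrices import build_texture_matrices
from radepi.features.quantize import QuantizationConfig, quantize_intensities
from radepi.features.registry import FEATURE_REGISTRY, INTENSITY_FAMILIES, WAVELET_BANDS
from radepi.features.shape import extract_shape
from radepi.features.texture import texture_features
from radepi.features.wavelet import decompose
from radepi.volume import ImageVolume, RoiMask

#: Ordered feature name -> value mapping; extract_all always returns 734 entries.
FeatureVector = OrderedDict


def _intensity_families(
    image: np.ndarray, mask: RoiMask, q: QuantizationConfig
) -> dict[str, dict[str, float]]:
    """FOS + the four texture families for one (sub-band) image."""
    out = {"FOS": extract_fos(image, mask, q)}
    levels = quantize_intensities(image, mask, q)
    out.update(texture_features(build_texture_matrices(levels, q.n_levels)))
    return out


def extract_all(
    volume: ImageVolume,
    mask: RoiMask,
    ac_mm,
    q: QuantizationConfig = QuantizationConfig(),
    study_id: str = "<study>",
) -> "OrderedDict[str, float]":
    """The ordered 734-entry radiomic feature vector of one study.

    Location and shape features are computed once on the original geometry;
    the 5 intensity families (17 FOS + 63 texture features) are computed on
    the original image and on each of the 8 Coiflet-1 sub-bands, which are
    quantized independently.

    Raises
    ------
    ValueError
        If grids disagree, the mask is empty, or any feature comes out
        non-finite (the error names the feature and the study).
    """
    mask.check_grid(volume)
    centroid = compute_centroid(mask, volume, study_id)
    location = extract_location_features(centroid, np.asarray(ac_mm, dtype=float)).as_dict()
    shape = extract_shape(mask, volume.voxel_spacing)

    per_image: dict[str, dict[str, dict[str, float]]] = {
        "original": _intensity_families(volume.intensities, mask, q)
    }
    bands = decompose(volume.intensities)
    for band in WAVELET_BANDS:
        per_image[f"Coiflet_{band}"] = _intensity_families(bands[band], mask, q)

    values = OrderedDict()
    for name in FEATURE_REGISTRY:
        image, family, feature = _split(name)
        if family == "location":
            v = location[feature]
        elif family == "shape":
            v = shape[feature]
        else:
            v = per_image[image][family][feature]
        if not np.isfinite(v):
            raise ValueError(f"non-finite feature {name} for study {study_id}")
        values[name] = float(v)
    return values


def _split(name: str) -> tuple[str, str, str]:
    from radepi.features.registry import parse_feature_name

    return parse_feature_name(name)
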