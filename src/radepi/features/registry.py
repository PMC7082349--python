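"""Versioned catalogue of the 734 radiomic feature names.

The registry is the authoritative local definition of the feature
inventory: 6 location + 17 first-order + 8 shape + 63 texture features on
the original image, plus (17 + 63) x 8 = 640 features on the Coiflet-1
wavelet sub-bands.

Name schema: ``<image>_<family>_<feature>`` where ``<image>`` is
``original`` or ``Coiflet_<band>`` with band in LLL..HHH, e.g.
``Coiflet_LLL_GLSZM_zone_percentage``.
"""

from __future__ import annotations

import json

from radepi.features.firstorder import FOS_NAMES
from radepi.features.shape import SHAPE_NAMES

REGISTRY_VERSION = "1.0"

LOCATION_NAMES: tuple[str, ...] = (
    "r",
    "theta",
    "phi",
    "city_block",
    "chebyshev",
    "euclidean",
)

GLCM_NAMES: tuple[str, ...] = (
    "autocorrelation",
    "joint_average",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "joint_energy",
    "joint_entropy",
    "imc1",
    "imc2",
    "inverse_difference_moment",
    "inverse_difference_moment_normalized",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "sum_of_squares",
    "dissimilarity",
    "maximal_correlation_coefficient",
)

GLRLM_NAMES: tuple[str, ...] = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized",
    "run_length_nonuniformity",
    "run_length_nonuniformity_normalized",
    "run_percentage",
    "gray_level_variance",
    "run_length_variance",
    "run_entropy",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
)

GLSZM_NAMES: tuple[str, ...] = (
    "small_area_emphasis",
    "large_area_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized",
    "size_zone_nonuniformity",
    "size_zone_nonuniformity_normalized",
    "zone_percentage",
    "gray_level_variance",
    "size_zone_variance",
    "zone_entropy",
    "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis",
    "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis",
    "large_area_high_gray_level_emphasis",
)

NGTDM_NAMES: tuple[str, ...] = (
    "coarseness",
    "contrast",
    "busyness",
    "complexity",
    "strength",
)

WAVELET_BANDS: tuple[str, ...] = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

#: Families and their per-image feature name lists.
FAMILY_NAMES: dict[str, tuple[str, ...]] = {
    "location": LOCATION_NAMES,
    "FOS": FOS_NAMES,
    "shape": SHAPE_NAMES,
    "GLCM": GLCM_NAMES,
    "GLRLM": GLRLM_NAMES,
    "GLSZM": GLSZM_NAMES,
    "NGTDM": NGTDM_NAMES,
}

#: Family counts of the full inventory (original + wavelet).
FAMILY_COUNTS: dict[str, int] = {
    "location": 6,
    "FOS": 17,
    "shape": 8,
    "GLCM": 26,
    "GLRLM": 16,
    "GLSZM": 16,
    "NGTDM": 5,
    "wavelet": 640,
}

#: Families recomputed on every wavelet sub-band (not shape/location).
INTENSITY_FAMILIES: tuple[str, ...] = ("FOS", "GLCM", "GLRLM", "GLSZM", "NGTDM")


def feature_names() -> list[str]:
    """The 734 feature names in canonical order.

    Order: location, FOS, shape, GLCM, GLRLM, GLSZM, NGTDM on the original
    image, then the five intensity families per wavelet band LLL..HHH.
    """
    names: list[str] = []
    for family in ("location", "FOS", "shape", "GLCM", "GLRLM", "GLSZM", "NGTDM"):
        names.extend(f"original_{family}_{f}" for f in FAMILY_NAMES[family])
    for band in WAVELET_BANDS:
        for family in INTENSITY_FAMILIES:
            names.extend(f"Coiflet_{band}_{family}_{f}" for f in FAMILY_NAMES[family])
    return names


FEATURE_REGISTRY: tuple[str, ...] = tuple(feature_names())

assert len(FEATURE_REGISTRY) == 734, len(FEATURE_REGISTRY)
assert len(set(FEATURE_REGISTRY)) == 734


def parse_feature_name(name: str) -> tuple[str, str, str]:
    """Split a registry name into (image, family, feature)."""
    if name.startswith("original_"):
        rest = name[len("original_") :]
        image = "original"
    elif name.startswith("Coiflet_"):
        band = name.split("_")[1]
        image = f"Coiflet_{band}"
        rest = name[len(image) + 1 :]
    else:
        raise ValueError(f"not a registry feature name: {name}")
    family, feature = rest.split("_", 1)
    return image, family, feature


def registry_as_json() -> str:
    """Serializable description of the registry (names, families, version)."""
    return json.dumps(
        {
            "version": REGISTRY_VERSION,
            "n_features": len(FEATURE_REGISTRY),
            "family_counts": FAMILY_COUNTS,
            "conventions": {
                "quantization": "equal-width, 32 levels over within-ROI min..max, per image",
                "glcm_glrlm_directions": "13 unique 3D distance-1 directions, averaged",
                "glszm_ngtdm_connectivity": 26,
                "wavelet": "Coiflet-1, one-level undecimated separable 3D transform",
                "degenerate_single_level": "correlation-type GLCM features = 0",
                "surface": "voxel-face surface area",
            },
            "names": list(FEATURE_REGISTRY),
        },
        indent=2,
    )
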