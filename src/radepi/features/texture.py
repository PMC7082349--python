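"""Texture features computed from GLCM/GLRLM/GLSZM/NGTDM matrices.

The catalogue (26 + 16 + 16 + 5 = 63 features) follows the standard
IBSI-style definitions; the exact list and conventions live in
:mod:`radepi.features.registry`. Directional families (GLCM, GLRLM) are
computed per direction and averaged over the 13 directions; directions
that observed no voxel pair/run are skipped in the average.

Degenerate single-gray-level ROIs: correlation-type GLCM features
(correlation, the two informational measures and the maximal correlation
coefficient) are defined as 0 rather than NaN so they cannot poison
downstream selection.
"""

from __future__ import annotations

import numpy as np

from radepi.features.matrices import TextureMatrices

_EPS = np.finfo(float).eps


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with 0 log 0 = 0."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


# ---------------------------------------------------------------------------
# GLCM (26 features per direction, averaged)
# ---------------------------------------------------------------------------

def glcm_features_single(p: np.ndarray) -> dict[str, float]:
    """The 26 GLCM features of one symmetric, normalized co-occurrence matrix."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)  # marginal; == py by symmetry
    mu_x = float(np.sum(i * px))
    sigma_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))

    # diagonal and cross-diagonal distributions
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj - 2).ravel(), p.ravel())
    k_diff = np.arange(0, ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())

    hxy = float(-np.sum(_xlog2(p)))
    hx = float(-np.sum(_xlog2(px)))
    px_py = np.outer(px, px)
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = float(-np.sum(np.where(px_py > 0, p * np.log2(px_py + (px_py <= 0)), 0.0)))
        hxy2 = float(-np.sum(_xlog2(px_py)))

    diff_avg = float(np.sum(k_diff * p_diff))
    sum_avg = float(np.sum(k_sum * p_sum))

    feats: dict[str, float] = {}
    feats["autocorrelation"] = float(np.sum(ii * jj * p))
    feats["joint_average"] = mu_x
    feats["cluster_prominence"] = float(np.sum((ii + jj - 2 * mu_x) ** 4 * p))
    feats["cluster_shade"] = float(np.sum((ii + jj - 2 * mu_x) ** 3 * p))
    feats["cluster_tendency"] = float(np.sum((ii + jj - 2 * mu_x) ** 2 * p))
    feats["contrast"] = float(np.sum((ii - jj) ** 2 * p))
    if sigma_x > 0:
        feats["correlation"] = float((np.sum(ii * jj * p) - mu_x * mu_x) / (sigma_x * sigma_x))
    else:
        feats["correlation"] = 0.0
    feats["difference_average"] = diff_avg
    feats["difference_entropy"] = float(-np.sum(_xlog2(p_diff)))
    feats["difference_variance"] = float(np.sum((k_diff - diff_avg) ** 2 * p_diff))
    feats["joint_energy"] = float(np.sum(p * p))
    feats["joint_entropy"] = hxy
    feats["imc1"] = float((hxy - hxy1) / hx) if hx > 0 else 0.0
    feats["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    feats["inverse_difference_moment"] = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    feats["inverse_difference_moment_normalized"] = float(
        np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))
    )
    feats["inverse_difference"] = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    feats["inverse_difference_normalized"] = float(np.sum(p / (1.0 + np.abs(ii - jj) / ng)))
    off = ii != jj
    feats["inverse_variance"] = float(np.sum(p[off] / (ii[off] - jj[off]) ** 2))
    feats["maximum_probability"] = float(p.max())
    feats["sum_average"] = sum_avg
    feats["sum_entropy"] = float(-np.sum(_xlog2(p_sum)))
    feats["sum_variance"] = float(np.sum((k_sum - sum_avg) ** 2 * p_sum))
    feats["sum_of_squares"] = float(np.sum((ii - mu_x) ** 2 * p))
    feats["dissimilarity"] = float(np.sum(np.abs(ii - jj) * p))
    feats["maximal_correlation_coefficient"] = _glcm_mcc(p, px)
    return feats


def _glcm_mcc(p: np.ndarray, px: np.ndarray) -> float:
    """Square root of the second-largest eigenvalue of the Markov kernel Q."""
    occ = px > 0
    if occ.sum() < 2:
        return 0.0  # degenerate single-level convention
    ps = p[np.ix_(occ, occ)]
    mx = px[occ]
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) px(k))
    q = (ps / mx[:, None]) @ (ps / mx[None, :]).T
    ev = np.linalg.eigvals(q)
    ev = np.sort(np.abs(ev))
    second = ev[-2] if len(ev) >= 2 else 0.0
    return float(np.sqrt(max(0.0, min(1.0, second))))


# ---------------------------------------------------------------------------
# GLRLM / GLSZM (shared algebra over a (level, length-or-size) count matrix)
# ---------------------------------------------------------------------------

def _rl_sz_features(m: np.ndarray, n_voxels: int, prefix_small: str, prefix_large: str,
                    count_name: str, axis_name: str) -> dict[str, float]:
    """Features over a count matrix with rows = gray level, cols = run length or zone size."""
    ns = float(m.sum())
    if ns == 0:
        return {}
    ng, lmax = m.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, lmax + 1)[None, :].astype(float)
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    pm = m / ns
    mu_i = float(np.sum(i * pm))
    mu_j = float(np.sum(j * pm))

    feats = {
        prefix_small: float(np.sum(m / j**2) / ns),
        prefix_large: float(np.sum(m * j**2) / ns),
        "gray_level_nonuniformity": float(np.sum(row**2) / ns),
        "gray_level_nonuniformity_normalized": float(np.sum(row**2) / ns**2),
        f"{axis_name}_nonuniformity": float(np.sum(col**2) / ns),
        f"{axis_name}_nonuniformity_normalized": float(np.sum(col**2) / ns**2),
        f"{count_name}_percentage": float(ns / n_voxels),
        "gray_level_variance": float(np.sum((i - mu_i) ** 2 * pm)),
        f"{axis_name}_variance": float(np.sum((j - mu_j) ** 2 * pm)),
        f"{count_name}_entropy": float(-np.sum(_xlog2(pm))),
        "low_gray_level_emphasis": float(np.sum(m / i**2) / ns),
        "high_gray_level_emphasis": float(np.sum(m * i**2) / ns),
        f"{prefix_small}_low_gray_level": float(np.sum(m / (i**2 * j**2)) / ns),
        f"{prefix_small}_high_gray_level": float(np.sum(m * i**2 / j**2) / ns),
        f"{prefix_large}_low_gray_level": float(np.sum(m * j**2 / i**2) / ns),
        f"{prefix_large}_high_gray_level": float(np.sum(m * i**2 * j**2) / ns),
    }
    return feats


def glrlm_features_single(m: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 GLRLM features of one direction's run-count matrix."""
    raw = _rl_sz_features(
        m, n_voxels, "short_run_emphasis", "long_run_emphasis", "run", "run_length"
    )
    if not raw:
        return {}
    return {
        "short_run_emphasis": raw["short_run_emphasis"],
        "long_run_emphasis": raw["long_run_emphasis"],
        "gray_level_nonuniformity": raw["gray_level_nonuniformity"],
        "gray_level_nonuniformity_normalized": raw["gray_level_nonuniformity_normalized"],
        "run_length_nonuniformity": raw["run_length_nonuniformity"],
        "run_length_nonuniformity_normalized": raw["run_length_nonuniformity_normalized"],
        "run_percentage": raw["run_percentage"],
        "gray_level_variance": raw["gray_level_variance"],
        "run_length_variance": raw["run_length_variance"],
        "run_entropy": raw["run_entropy"],
        "low_gray_level_run_emphasis": raw["low_gray_level_emphasis"],
        "high_gray_level_run_emphasis": raw["high_gray_level_emphasis"],
        "short_run_low_gray_level_emphasis": raw["short_run_emphasis_low_gray_level"],
        "short_run_high_gray_level_emphasis": raw["short_run_emphasis_high_gray_level"],
        "long_run_low_gray_level_emphasis": raw["long_run_emphasis_low_gray_level"],
        "long_run_high_gray_level_emphasis": raw["long_run_emphasis_high_gray_level"],
    }


def glszm_features(m: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 GLSZM features of the zone-count matrix."""
    raw = _rl_sz_features(
        m, n_voxels, "small_area_emphasis", "large_area_emphasis", "zone", "size_zone"
    )
    if not raw:
        return {}
    return {
        "small_area_emphasis": raw["small_area_emphasis"],
        "large_area_emphasis": raw["large_area_emphasis"],
        "gray_level_nonuniformity": raw["gray_level_nonuniformity"],
        "gray_level_nonuniformity_normalized": raw["gray_level_nonuniformity_normalized"],
        "size_zone_nonuniformity": raw["size_zone_nonuniformity"],
        "size_zone_nonuniformity_normalized": raw["size_zone_nonuniformity_normalized"],
        "zone_percentage": raw["zone_percentage"],
        "gray_level_variance": raw["gray_level_variance"],
        "size_zone_variance": raw["size_zone_variance"],
        "zone_entropy": raw["zone_entropy"],
        "low_gray_level_zone_emphasis": raw["low_gray_level_emphasis"],
        "high_gray_level_zone_emphasis": raw["high_gray_level_emphasis"],
        "small_area_low_gray_level_emphasis": raw["small_area_emphasis_low_gray_level"],
        "small_area_high_gray_level_emphasis": raw["small_area_emphasis_high_gray_level"],
        "large_area_low_gray_level_emphasis": raw["large_area_emphasis_low_gray_level"],
        "large_area_high_gray_level_emphasis": raw["large_area_emphasis_high_gray_level"],
    }


# ---------------------------------------------------------------------------
# NGTDM (5 features, Amadasun-King)
# ---------------------------------------------------------------------------

def ngtdm_features(p: np.ndarray, s: np.ndarray, n: np.ndarray) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength from (p_i, s_i)."""
    occ = p > 0
    levels = np.arange(1, len(p) + 1, dtype=float)
    n_total = float(n.sum())
    ngp = int(occ.sum())

    ps = float(np.sum(p * s))
    coarseness = float(1.0 / ps) if ps > 0 else 1e6  # capped when all s_i = 0

    if ngp > 1 and n_total > 0:
        li, lj = np.meshgrid(levels[occ], levels[occ], indexing="ij")
        pi_, pj_ = np.meshgrid(p[occ], p[occ], indexing="ij")
        contrast = float(
            np.sum(pi_ * pj_ * (li - lj) ** 2) / (ngp * (ngp - 1)) * (s.sum() / n_total)
        )
        denom_busy = float(np.sum(np.abs(li * pi_ - lj * pj_)))
        busyness = float(ps / denom_busy) if denom_busy > 0 else 0.0
        si_, sj_ = np.meshgrid(s[occ], s[occ], indexing="ij")
        complexity = float(
            np.sum(np.abs(li - lj) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)) / n_total
        )
        strength = (
            float(np.sum((pi_ + pj_) * (li - lj) ** 2) / s.sum()) if s.sum() > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def texture_features(matrices: TextureMatrices) -> dict[str, dict[str, float]]:
    """All 63 texture features, keyed by family (GLCM/GLRLM/GLSZM/NGTDM).

    GLCM and GLRLM features are averaged over the directions that observed
    at least one pair/run.
    """
    glcm_per_dir = [
        glcm_features_single(matrices.glcm[k])
        for k in range(matrices.glcm.shape[0])
        if matrices.glcm[k].sum() > 0
    ]
    glrlm_per_dir = [
        feats
        for k in range(matrices.glrlm.shape[0])
        if (feats := glrlm_features_single(matrices.glrlm[k], matrices.n_voxels))
    ]

    def average(dicts: list[dict[str, float]], names: tuple[str, ...]) -> dict[str, float]:
        if not dicts:  # single-voxel ROI: no pairs/runs in any direction
            return {k: 0.0 for k in names}
        keys = dicts[0].keys()
        return {k: float(np.mean([d[k] for d in dicts])) for k in keys}

    from radepi.features.registry import GLCM_NAMES, GLRLM_NAMES

    return {
        "GLCM": average(glcm_per_dir, GLCM_NAMES),
        "GLRLM": average(glrlm_per_dir, GLRLM_NAMES),
        "GLSZM": glszm_features(matrices.glszm, matrices.n_voxels),
        "NGTDM": ngtdm_features(matrices.ngtdm_p, matrices.ngtdm_s, matrices.ngtdm_n),
    }
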