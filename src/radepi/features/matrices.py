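"""Texture matrices: GLCM, GLRLM, GLSZM and NGTDM on quantized 3D ROIs.

All matrices follow the standard 3D conventions:

* GLCM / GLRLM: the 13 unique distance-1 voxel directions (one per
  antipodal pair of the 26-neighborhood). GLCMs are symmetric and
  normalized per direction; GLRLMs count each maximal run once per
  direction.
* GLSZM: zones are 26-connected components of equal gray level.
* NGTDM: neighborhood means over the 26-neighborhood restricted to the
  ROI; ``p_i`` are level occurrence probabilities among voxels with at
  least one valid neighbor, ``s_i`` the summed absolute differences from
  the neighborhood mean.

Voxel offsets are in grid steps (no mm weighting), matching the
no-resampling policy: anisotropic geometry enters only through location
and shape features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: The 13 unique distance-1 directions in 3D (antipodal duplicates removed,
#: first nonzero component positive).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class TextureMatrices:
    """Container for all four texture matrices of one quantized ROI.

    Attributes
    ----------
    glcm
        (13, Ng, Ng) per-direction symmetric probability matrices.
    glcm_mean
        (Ng, Ng) direction-averaged probability matrix.
    glrlm
        (13, Ng, Lmax) per-direction run-count matrices.
    glszm
        (Ng, Zmax) zone-count matrix.
    ngtdm_p, ngtdm_s, ngtdm_n
        Per-level occurrence probabilities, summed absolute neighborhood
        differences and voxel counts (arrays of length Ng, index = level-1).
    n_levels, n_voxels
        Quantization depth and ROI voxel count.
    """

    glcm: np.ndarray
    glcm_mean: np.ndarray
    glrlm: np.ndarray
    glszm: np.ndarray
    ngtdm_p: np.ndarray
    ngtdm_s: np.ndarray
    ngtdm_n: np.ndarray
    n_levels: int
    n_voxels: int


def _shift_view(shape: tuple[int, ...], d: tuple[int, int, int]):
    """Slices (src, dst) so that levels[src] and levels[dst] are voxel pairs offset by d."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif step == 1:
            src.append(slice(0, n - 1))
            dst.append(slice(1, n))
        else:
            src.append(slice(1, n))
            dst.append(slice(0, n - 1))
    return tuple(src), tuple(dst)


def compute_glcm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Per-direction symmetric normalized GLCMs, shape (13, Ng, Ng).

    A direction with no in-ROI voxel pair yields an all-zero matrix.
    """
    out = np.zeros((len(DIRECTIONS_13), n_levels, n_levels))
    for k, d in enumerate(DIRECTIONS_13):
        src, dst = _shift_view(levels.shape, d)
        a = levels[src].ravel()
        b = levels[dst].ravel()
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        a, b = a[ok] - 1, b[ok] - 1
        m = np.bincount(a * n_levels + b, minlength=n_levels * n_levels).reshape(
            n_levels, n_levels
        ).astype(float)
        m = m + m.T  # symmetric: count both orders
        out[k] = m / m.sum()
    return out


def compute_glrlm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Per-direction gray-level run-length count matrices, shape (13, Ng, Lmax).

    A run is a maximal set of collinear, contiguous, equal-level ROI voxels
    along the direction; each run of length L contributes one count at
    (level, L). Lmax is the largest grid extent.
    """
    lmax = max(levels.shape)
    out = np.zeros((len(DIRECTIONS_13), n_levels, lmax))
    for k, d in enumerate(DIRECTIONS_13):
        run_len = _run_lengths(levels, d)
        # a run starts where the predecessor (v - d) is off-grid/ROI or differs
        src, dst = _shift_view(levels.shape, d)
        same_prev = np.zeros(levels.shape, dtype=bool)
        same_prev[dst] = (levels[dst] == levels[src]) & (levels[src] > 0)
        starts = (levels > 0) & ~same_prev
        lv = levels[starts] - 1
        ln = run_len[starts] - 1
        np.add.at(out[k], (lv, ln), 1.0)
    return out


def _run_lengths(levels: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """For every ROI voxel, length of the equal-level run extending from it along +d."""
    run = (levels > 0).astype(np.int64)
    axis = next(i for i, s in enumerate(d) if s != 0)
    n = levels.shape[axis]
    # process slices along `axis` so that slice i depends on the already
    # computed slice i + d[axis]
    order = range(n - 2, -1, -1) if d[axis] == 1 else range(1, n)

    def take(arr, i):
        sl = [slice(None)] * 3
        sl[axis] = i
        return arr[tuple(sl)]

    for i in order:
        j = i + d[axis]
        cur = take(levels, i)
        nxt_levels = take(levels, j)
        nxt_run = take(run, j)
        # shift within the slice for the remaining direction components
        shift = [s for a, s in enumerate(d) if a != axis]
        nxt_levels = _shift2d(nxt_levels, shift, fill=0)
        nxt_run = _shift2d(nxt_run, shift, fill=0)
        same = (cur > 0) & (cur == nxt_levels)
        take(run, i)[same] += nxt_run[same]
    return run


def _shift2d(arr: np.ndarray, shift: list[int], fill=0) -> np.ndarray:
    """Shift a 2D array by -shift (content moves so element at +shift lands at origin)."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for n, s in zip(arr.shape, shift):
        if s == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif s == 1:
            src.append(slice(1, n))
            dst.append(slice(0, n - 1))
        else:
            src.append(slice(0, n - 1))
            dst.append(slice(1, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def compute_glszm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Gray-level size-zone count matrix, shape (Ng, Zmax).

    Zones are 26-connected components of equal level within the ROI.
    """
    counts: dict[tuple[int, int], int] = {}
    zmax = 1
    for level in np.unique(levels[levels > 0]):
        labeled, n_zones = ndimage.label(levels == level, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for size in sizes:
            counts[(int(level), int(size))] = counts.get((int(level), int(size)), 0) + 1
            zmax = max(zmax, int(size))
    out = np.zeros((n_levels, zmax))
    for (level, size), c in counts.items():
        out[level - 1, size - 1] = c
    return out


def compute_ngtdm(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NGTDM components (p_i, s_i, n_i), each of length Ng.

    For every ROI voxel with at least one ROI neighbor in its
    26-neighborhood, the absolute difference between its level and the mean
    level of those neighbors is accumulated into ``s`` at its level;
    ``n_i`` counts such voxels and ``p_i = n_i / sum(n)``.
    """
    inside = levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    neighbor_sum = ndimage.correlate(levels.astype(float) * inside, kernel, mode="constant")
    neighbor_cnt = ndimage.correlate(inside.astype(float), kernel, mode="constant")
    valid = inside & (neighbor_cnt > 0)
    diffs = np.zeros(levels.shape)
    diffs[valid] = np.abs(levels[valid] - neighbor_sum[valid] / neighbor_cnt[valid])

    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    lv = levels[valid] - 1
    np.add.at(s, lv, diffs[valid])
    np.add.at(n, lv, 1.0)
    total = n.sum()
    p = n / total if total > 0 else n
    return p, s, n


def build_texture_matrices(levels: np.ndarray, n_levels: int) -> TextureMatrices:
    """All four texture matrices of one quantized ROI (0 = outside)."""
    glcm = compute_glcm(levels, n_levels)
    # average only over directions that observed at least one pair, so the
    # mean stays a probability matrix
    nonzero = glcm.sum(axis=(1, 2)) > 0
    glcm_mean = glcm[nonzero].mean(axis=0) if nonzero.any() else glcm.sum(axis=0)
    p, s, n = compute_ngtdm(levels, n_levels)
    return TextureMatrices(
        glcm=glcm,
        glcm_mean=glcm_mean,
        glrlm=compute_glrlm(levels, n_levels),
        glszm=compute_glszm(levels, n_levels),
        ngtdm_p=p,
        ngtdm_s=s,
        ngtdm_n=n,
        n_levels=n_levels,
        n_voxels=int((levels > 0).sum()),
    )
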