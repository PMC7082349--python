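"""Independent brute-force oracles for the texture matrices.

These deliberately use naive enumeration (explicit voxel loops, flood
fill) so they share no code with the vectorized implementations they
check.
"""

from __future__ import annotations

import numpy as np

from radepi.features.matrices import DIRECTIONS_13


def _in_bounds(p, shape) -> bool:
    return all(0 <= p[a] < shape[a] for a in range(3))


def naive_glcm(levels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Symmetric normalized GLCM for one direction by explicit pair scan."""
    m = np.zeros((n_levels, n_levels))
    shape = levels.shape
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        q = tuple(p[a] + direction[a] for a in range(3))
        if _in_bounds(q, shape) and levels[q] > 0:
            m[levels[p] - 1, levels[q] - 1] += 1
            m[levels[q] - 1, levels[p] - 1] += 1
    total = m.sum()
    return m / total if total > 0 else m


def naive_glrlm(levels: np.ndarray, n_levels: int, direction, lmax: int) -> np.ndarray:
    """Run-length counts for one direction by walking each maximal run."""
    m = np.zeros((n_levels, lmax))
    shape = levels.shape
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        prev = tuple(p[a] - direction[a] for a in range(3))
        if _in_bounds(prev, shape) and levels[prev] == levels[p]:
            continue  # not a run start
        length = 1
        q = tuple(p[a] + direction[a] for a in range(3))
        while _in_bounds(q, shape) and levels[q] == levels[p]:
            length += 1
            q = tuple(q[a] + direction[a] for a in range(3))
        m[levels[p] - 1, length - 1] += 1
    return m


def naive_glszm(levels: np.ndarray, n_levels: int) -> dict[tuple[int, int], int]:
    """Zone counts {(level, size): count} by 26-connected flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    neighbors = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    zones: dict[tuple[int, int], int] = {}
    for p in np.ndindex(shape):
        if levels[p] == 0 or seen[p]:
            continue
        level = levels[p]
        stack = [p]
        seen[p] = True
        size = 0
        while stack:
            v = stack.pop()
            size += 1
            for d in neighbors:
                q = tuple(v[a] + d[a] for a in range(3))
                if _in_bounds(q, shape) and not seen[q] and levels[q] == level:
                    seen[q] = True
                    stack.append(q)
        zones[(int(level), size)] = zones.get((int(level), size), 0) + 1
    return zones


def naive_ngtdm(levels: np.ndarray, n_levels: int):
    """(p_i, s_i, n_i) by per-voxel neighborhood enumeration."""
    shape = levels.shape
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    neighbors = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        vals = [
            levels[tuple(p[a] + d[a] for a in range(3))]
            for d in neighbors
            if _in_bounds(tuple(p[a] + d[a] for a in range(3)), shape)
        ]
        vals = [v for v in vals if v > 0]
        if not vals:
            continue
        s[levels[p] - 1] += abs(levels[p] - sum(vals) / len(vals))
        n[levels[p] - 1] += 1
    total = n.sum()
    p_i = n / total if total > 0 else n
    return p_i, s, n


def glszm_dict_to_matrix(zones: dict[tuple[int, int], int], n_levels: int) -> np.ndarray:
    zmax = max((size for (_, size) in zones), default=1)
    m = np.zeros((n_levels, zmax))
    for (level, size), c in zones.items():
        m[level - 1, size - 1] = c
    return m


def naive_pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by exhaustive concordance counting with 1/2 credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


__all__ = [
    "DIRECTIONS_13",
    "naive_glcm",
    "naive_glrlm",
    "naive_glszm",
    "naive_ngtdm",
    "glszm_dict_to_matrix",
    "naive_pairwise_auc",
]
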