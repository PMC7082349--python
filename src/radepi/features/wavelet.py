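"""One-level 3D Coiflet-1 wavelet decomposition.

The transform is the undecimated (stationary) separable decomposition with
the orthogonal Coiflet-1 filter pair, using circular boundary handling.
Every sub-band lives on the input grid, so the original ROI mask applies
to all eight bands directly, and perfect reconstruction holds exactly:

    x = (1/8) * sum over bands of the matched time-reversed synthesis pass

(up to a circular shift that :func:`reconstruct` undoes).

The Coiflet-1 scaling filter has the closed form
``[-3+s, 1-s, 14-2s, 14+2s, 5+s, 1-s] / (16*sqrt(2))`` with ``s = sqrt(7)``;
the wavelet filter is its quadrature mirror. One vanishing moment makes the
seven detail bands of a constant volume vanish to machine precision.
"""

from __future__ import annotations

import numpy as np

_S7 = np.sqrt(7.0)
#: Coiflet-1 analysis low-pass filter (sums to sqrt(2)).
DEC_LO: np.ndarray = np.array(
    [-3.0 + _S7, 1.0 - _S7, 14.0 - 2.0 * _S7, 14.0 + 2.0 * _S7, 5.0 + _S7, 1.0 - _S7]
) / (16.0 * np.sqrt(2.0))
#: Quadrature-mirror high-pass filter.
DEC_HI: np.ndarray = np.array(
    [(-1.0) ** k * DEC_LO[len(DEC_LO) - 1 - k] for k in range(len(DEC_LO))]
)

BAND_ORDER: tuple[str, ...] = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def _circular_convolve(x: np.ndarray, h: np.ndarray, axis: int) -> np.ndarray:
    """Circular convolution y[i] = sum_j h[j] x[(i-j) mod n] along one axis."""
    n = x.shape[axis]
    if n < len(h):
        raise ValueError(
            f"axis {axis} has extent {n} < filter length {len(h)}; pad the volume first"
        )
    idx = (np.arange(n)[:, None] - np.arange(len(h))[None, :]) % n
    xm = np.moveaxis(x, axis, 0)
    y = np.tensordot(xm[idx], h, axes=([1], [0]))
    return np.moveaxis(y, 0, axis)


def decompose(volume: np.ndarray) -> dict[str, np.ndarray]:
    """Eight same-size sub-bands of a 3D volume, keyed LLL..HHH.

    Band letter k applies the low- (L) or high-pass (H) filter along axis k.
    """
    arr = np.asarray(volume, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {arr.shape}")
    crop = None
    if min(arr.shape) < len(DEC_LO):
        # symmetric-pad tiny volumes up to the filter length, crop bands back
        pads = [(0, max(0, len(DEC_LO) - n)) for n in arr.shape]
        crop = tuple(slice(0, n) for n in arr.shape)
        arr = np.pad(arr, pads, mode="symmetric")
    # cascade axis by axis so each filter pass is done once per intermediate
    lo0 = _circular_convolve(arr, DEC_LO, 0)
    hi0 = _circular_convolve(arr, DEC_HI, 0)
    bands: dict[str, np.ndarray] = {}
    for c0, half0 in (("L", lo0), ("H", hi0)):
        lo1 = _circular_convolve(half0, DEC_LO, 1)
        hi1 = _circular_convolve(half0, DEC_HI, 1)
        for c1, half1 in (("L", lo1), ("H", hi1)):
            bands[f"{c0}{c1}L"] = _circular_convolve(half1, DEC_LO, 2)
            bands[f"{c0}{c1}H"] = _circular_convolve(half1, DEC_HI, 2)
    if crop is not None:
        bands = {b: v[crop] for b, v in bands.items()}
    return {b: bands[b] for b in BAND_ORDER}


def reconstruct(bands: dict[str, np.ndarray]) -> np.ndarray:
    """Invert :func:`decompose` exactly (to numerical precision)."""
    if set(bands) != set(BAND_ORDER):
        raise ValueError(f"expected bands {BAND_ORDER}, got {sorted(bands)}")
    shift = len(DEC_LO) - 1
    rec = np.zeros_like(next(iter(bands.values())))
    for code, band in bands.items():
        r = band
        for axis, c in enumerate(code):
            h = DEC_LO if c == "L" else DEC_HI
            r = _circular_convolve(r, h[::-1], axis)
        rec += r
    rec /= 8.0
    return np.roll(rec, shift=(-shift, -shift, -shift), axis=(0, 1, 2))
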