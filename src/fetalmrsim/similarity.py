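"""Masked mutual information between co-gridded volumes.

Used to quantify how close two reconstructions of the same subject are,
typically restricted to the white matter mask.  Intensities are min-max
scaled within the mask and histogrammed on 64 equal-width bins (the
binning is configurable); MI is reported in bits.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._errors import GeometryError, ValidationError


def _scaled(vals: np.ndarray) -> np.ndarray:
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        return np.zeros_like(vals)
    return (vals - lo) / (hi - lo)


def mutual_information(vol_a: np.ndarray, vol_b: np.ndarray,
                       mask: np.ndarray, n_bins: int = 64) -> float:
    """MI (bits) of the joint intensity histogram within ``mask``.

    Symmetric in its arguments and non-negative.  A volume that is
    constant within the mask has zero marginal entropy; MI is then 0 and
    a warning is issued.
    """
    vol_a, vol_b = np.asarray(vol_a), np.asarray(vol_b)
    mask = np.asarray(mask, dtype=bool)
    if vol_a.shape != vol_b.shape or vol_a.shape != mask.shape:
        raise GeometryError("volumes and mask must share one grid")
    n = int(mask.sum())
    if n < 100:
        raise ValidationError(f"mask has {n} voxels; at least 100 required")
    a = vol_a[mask].astype(np.float64)
    b = vol_b[mask].astype(np.float64)
    if a.min() == a.max() or b.min() == b.max():
        warnings.warn("constant volume within mask: MI is 0", stacklevel=2)
        return 0.0
    if a.tobytes() > b.tobytes():   # canonical order: bit-exact symmetry
        a, b = b, a
    hist, _, _ = np.histogram2d(_scaled(a), _scaled(b), bins=n_bins,
                                range=[[0, 1], [0, 1]])
    p = hist / hist.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    terms = p[nz] * np.log2(p[nz] / (pa @ pb)[nz])
    # summing in sorted order makes MI(a, b) == MI(b, a) bit-exact
    mi = float(np.sort(terms).sum())
    return max(mi, 0.0)


def entropy_bits(vol: np.ndarray, mask: np.ndarray, n_bins: int = 64) -> float:
    """Marginal entropy (bits) under the same scaling/binning as MI."""
    vals = np.asarray(vol)[np.asarray(mask, dtype=bool)].astype(np.float64)
    if vals.min() == vals.max():
        return 0.0
    hist, _ = np.histogram(_scaled(vals), bins=n_bins, range=(0, 1))
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))
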