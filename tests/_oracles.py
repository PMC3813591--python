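"""Independent oracle implementations used only by the tests.

These deliberately share no code with the package: the brute-force
prominence search enumerates super-level components per threshold level
with scipy labeling, instead of the package's union-find sweep.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EIGHT = np.ones((3, 3), dtype=bool)


def brute_force_maxima(img, mask=None, tolerance=0.0, min_peak_value=None):
    """Exhaustive regional-maximum + prominence search.

    A regional maximum is a connected plateau (8-connectivity, within the
    mask) with no higher neighbor in the mask.  Its prominence is
    peak − t*, where t* is the highest threshold at which the super-level
    component containing it includes a strictly higher pixel; if no such
    level exists the prominence is peak − min over the mask component.
    Returns the set of lexicographically-smallest plateau pixels of maxima
    with prominence strictly above ``tolerance``.
    """
    img = np.asarray(img, dtype=float)
    if mask is None:
        mask = np.ones_like(img, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    h, w = img.shape
    if not mask.any():
        return set()

    levels = np.unique(img[mask])[::-1]  # descending
    # super-level components and their maxima, per level
    comp_by_level = {}
    for t in levels:
        lab, n = ndimage.label((img >= t) & mask, structure=_EIGHT)
        comp_max = ndimage.maximum(img, lab, index=np.arange(1, n + 1)) \
            if n else np.array([])
        comp_by_level[t] = (lab, comp_max)

    dom_lab, dom_n = ndimage.label(mask, structure=_EIGHT)
    dom_min = ndimage.minimum(np.where(mask, img, np.inf), dom_lab,
                              index=np.arange(1, dom_n + 1))

    results = set()
    for v in levels:
        plateau_lab, n_plateau = ndimage.label((img == v) & mask,
                                               structure=_EIGHT)
        for k in range(1, n_plateau + 1):
            plateau = plateau_lab == k
            ring = ndimage.binary_dilation(plateau, structure=_EIGHT) \
                & ~plateau & mask
            if ring.any() and img[ring].max() > v:
                continue  # not a regional maximum
            rows, cols = np.nonzero(plateau)
            i = np.lexsort((cols, rows))[0]
            rep = (int(rows[i]), int(cols[i]))
            prominence = None
            for t in levels:
                if t > v:
                    continue
                lab, comp_max = comp_by_level[t]
                c = lab[rep]
                if comp_max[c - 1] > v:
                    prominence = v - t
                    break
            if prominence is None:
                prominence = v - dom_min[dom_lab[rep] - 1]
            if prominence > tolerance and (min_peak_value is None
                                           or v >= min_peak_value):
                results.add(rep)
    return results


def mask_period_by_autocorrelation(mask, orientation_deg):
    """Measure a stripe mask's period along its normal by brute-force 1-D
    autocorrelation of the projected profile."""
    import math

    mask = np.asarray(mask, dtype=float)
    h, w = mask.shape
    rows, cols = np.mgrid[0:h, 0:w]
    theta = math.radians(orientation_deg)
    u = rows * math.cos(theta) - cols * math.sin(theta)
    bins = np.round(u - u.min()).astype(int)
    profile = np.bincount(bins.ravel(), weights=mask.ravel()) / \
        np.maximum(np.bincount(bins.ravel()), 1)
    x = profile - profile.mean()
    n = len(x)
    ac = np.array([np.dot(x[:n - lag], x[lag:]) / (n - lag)
                   for lag in range(n // 2)])
    # global maximum after the first zero crossing = one full period
    neg = np.nonzero(ac < 0)[0]
    start = int(neg[0]) if len(neg) else 1
    return int(start + np.argmax(ac[start:]))
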