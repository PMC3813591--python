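"""Mask generation and six-way mask algebra for striped fields of view.

The decomposition follows the working logic of striped micropattern
experiments: the stripe channel is thresholded into stamped/overlay
classes, the immunolabel channel into a mask of all cells (background = its
complement), the tracer channel splits cells into labeled/unlabeled, and
the pairwise intersections give six masks that partition the frame exactly.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .datatypes import MaskSet
from .errors import DegenerateThresholdError, ShapeMismatchError

_EIGHT = np.ones((3, 3), dtype=bool)


def compute_threshold(channel: np.ndarray, method: str = "otsu",
                      value: Optional[float] = None) -> float:
    """Resolve the threshold value for a channel.

    Otsu requires a non-constant channel; a constant channel raises
    :class:`DegenerateThresholdError` instead of silently producing an
    empty or full mask.
    """
    channel = np.asarray(channel)
    if np.any(channel < 0):
        raise ValueError("channel must be nonnegative")
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        return float(value)
    if method == "otsu":
        if channel.max() == channel.min():
            raise DegenerateThresholdError(
                "degenerate threshold: channel is constant-valued")
        return float(threshold_otsu(channel))
    raise ValueError(f"unknown threshold method {method!r}")


def threshold_mask(channel: np.ndarray, method: str = "otsu",
                   value: Optional[float] = None, min_object_px: int = 0,
                   fill_holes: bool = False) -> np.ndarray:
    """Binary mask = channel > threshold, with optional hole filling and
    removal of connected components smaller than ``min_object_px``."""
    thr = compute_threshold(channel, method, value)
    mask = np.asarray(channel) > thr
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if min_object_px > 1:
        # removes components with fewer than min_object_px pixels
        mask = remove_small_objects(mask, max_size=min_object_px - 1,
                                    connectivity=2)
    return mask


def build_mask_set(stripe_mask: np.ndarray, cell_mask: np.ndarray,
                   tracer_mask: Optional[np.ndarray] = None) -> MaskSet:
    """Combine the stripe, cell and (optional) tracer masks into the
    six-way :class:`MaskSet`.

    Without a tracer mask all cells are treated as a single "unlabeled"
    population.  ``cells_labeled = cell_mask ∧ tracer_mask`` and
    ``cells_unlabeled = cell_mask ∧ ¬tracer_mask``.
    """
    stripe_mask = np.asarray(stripe_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != stripe_mask.shape:
        raise ShapeMismatchError("cell mask shape differs from stripe mask")
    if tracer_mask is not None:
        tracer_mask = np.asarray(tracer_mask, dtype=bool)
        if tracer_mask.shape != stripe_mask.shape:
            raise ShapeMismatchError("tracer mask shape differs from stripe mask")
        labeled = cell_mask & tracer_mask
        unlabeled = cell_mask & ~tracer_mask
    else:
        labeled = np.zeros_like(cell_mask)
        unlabeled = cell_mask.copy()
    background = ~cell_mask
    overlay = ~stripe_mask
    combos = {}
    for pop, parent in (("labeled", labeled), ("unlabeled", unlabeled),
                        ("none", background)):
        for surf, smask in (("stamped", stripe_mask), ("overlay", overlay)):
            combos[(pop, surf)] = parent & smask
    return MaskSet(stamped=stripe_mask, overlay=overlay, cells_all=cell_mask,
                   cells_labeled=labeled, cells_unlabeled=unlabeled,
                   background=background, combos=combos)


def count_cells(cell_masks: dict, min_cell_area_um2: float,
                pixel_size_um: float) -> dict:
    """Count cells per population as 8-connected components with area of at
    least ``min_cell_area_um2``.  Touching cells merge into one component —
    a documented limitation of connected-component counting."""
    min_px = min_cell_area_um2 / pixel_size_um ** 2
    counts = {}
    for population, mask in cell_masks.items():
        lab, n = ndimage.label(np.asarray(mask, dtype=bool), structure=_EIGHT)
        if n == 0:
            counts[population] = 0
            continue
        sizes = np.bincount(lab.ravel())[1:]
        counts[population] = int(np.sum(sizes >= min_px))
    return counts
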