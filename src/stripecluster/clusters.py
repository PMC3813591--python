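"""Microcluster detection by prominence-filtered local maxima.

The detector mirrors the ImageJ "Find Maxima" idea: a regional maximum is
reported when its topographic prominence — the height drop to the highest
saddle that connects it to higher terrain — exceeds a noise tolerance.
Definitions used (8-connectivity, restricted to an analysis mask):

* A *regional maximum* is a maximal connected plateau of equal value with
  no higher neighbor inside the mask; its representative pixel is the
  lexicographically smallest (row, col) of the plateau.
* Its *prominence* is ``peak − saddle`` where the saddle is the highest
  level at which the super-level component containing the peak also
  contains a strictly higher pixel.  A maximum that never meets higher
  terrain (the global maximum of its mask component) has prominence
  ``peak − min`` over that component, so a perfectly flat region yields
  no maxima.
* Two equal-valued maxima that merge before meeting higher terrain share
  their (deeper) saddle and are both reported.

The implementation processes pixels level by level with a union-find
structure, which is exactly equivalent to the above definition.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import ClusterRecord, MaskSet
from .params import ClusterParams

logger = logging.getLogger(__name__)

_NEIGHBORS = ((-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1))


def robust_noise_scale(values: np.ndarray) -> float:
    """Normal-consistent median absolute deviation (1.4826 × MAD)."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def resolve_noise_tolerance(channel: np.ndarray, mask: np.ndarray,
                            params: ClusterParams) -> float:
    """Return the prominence tolerance, deriving it from the in-cell noise
    scale (``mad_k`` × robust sigma) when not set explicitly."""
    if params.noise_tolerance is not None:
        return float(params.noise_tolerance)
    sigma = robust_noise_scale(np.asarray(channel)[np.asarray(mask, bool)])
    if sigma <= 0:
        raise ValueError(
            "cannot derive a noise tolerance from constant in-cell values; "
            "set ClusterParams.noise_tolerance explicitly")
    return params.mad_k * sigma


def find_prominent_maxima(channel: np.ndarray, mask: Optional[np.ndarray],
                          noise_tolerance: float,
                          min_peak_value: Optional[float] = None,
                          return_prominence: bool = False):
    """All regional maxima inside ``mask`` with prominence strictly above
    ``noise_tolerance`` (and peak value >= ``min_peak_value`` if given).

    Returns an (N, 2) int array of representative (row, col) coordinates in
    lexicographic order, optionally together with the prominence of each.
    """
    img = np.asarray(channel, dtype=float)
    h, w = img.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    flat_v = img.ravel()
    domain = np.flatnonzero(mask.ravel())
    if domain.size == 0:
        empty = np.empty((0, 2), dtype=int)
        return (empty, np.empty(0)) if return_prominence else empty

    # process in descending value; ties in raster order for determinism
    order = domain[np.lexsort((domain, -flat_v[domain]))]

    n = flat_v.size
    parent = np.full(n, -1, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)
    peak_val = np.zeros(n, dtype=float)
    minv = np.zeros(n, dtype=float)
    lexmin = np.zeros(n, dtype=np.int64)
    alive: dict[int, list[int]] = {}
    finished: list[tuple[int, float, float]] = []  # (rep, prominence, peak)
    mask_flat = mask.ravel()

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return root

    def union(a: int, b: int, level: float) -> None:
        ra, rb = find(a), find(b)
        if ra == rb:
            return
        pa, pb = peak_val[ra], peak_val[rb]
        if pa > level and pb > level and pa != pb:
            low = ra if pa < pb else rb
            for rep in alive.pop(low, ()):  # key saddle of the lower peak
                finished.append((rep, peak_val[low] - level, peak_val[low]))
        if size[ra] < size[rb]:
            ra, rb = rb, ra
        parent[rb] = ra
        size[ra] += size[rb]
        peak_val[ra] = max(pa, pb)
        minv[ra] = level
        lexmin[ra] = min(lexmin[ra], lexmin[rb])
        merged = alive.pop(ra, []) + alive.pop(rb, [])
        if merged:
            alive[ra] = merged

    pos = 0
    m = order.size
    while pos < m:
        v = flat_v[order[pos]]
        end = pos
        while end < m and flat_v[order[end]] == v:
            end += 1
        batch = order[pos:end]
        for i in batch:  # activate the whole plateau level first
            parent[i] = i
            size[i] = 1
            peak_val[i] = v
            minv[i] = v
            lexmin[i] = i
        for i in batch:
            r, c = divmod(int(i), w)
            for dr, dc in _NEIGHBORS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    j = rr * w + cc
                    if mask_flat[j] and parent[j] != -1:
                        union(int(i), j, v)
        seen = set()
        for i in batch:
            root = find(int(i))
            if root in seen:
                continue
            seen.add(root)
            if peak_val[root] == v:  # plateau with no higher neighbor
                alive[root] = [int(lexmin[root])]
        pos = end

    for root, reps in alive.items():
        root = find(root)
        for rep in reps:
            finished.append((rep, peak_val[root] - minv[root], peak_val[root]))

    keep = [(rep, prom, pk) for rep, prom, pk in finished
            if prom > noise_tolerance
            and (min_peak_value is None or pk >= min_peak_value)]
    keep.sort(key=lambda t: t[0])
    coords = np.array([divmod(rep, w) for rep, _, _ in keep],
                      dtype=int).reshape(-1, 2)
    if return_prominence:
        return coords, np.array([prom for _, prom, _ in keep])
    return coords


def detect_maxima(label_channel: np.ndarray, cells_mask: np.ndarray,
                  params: ClusterParams) -> np.ndarray:
    """Detect candidate microcluster peaks inside the cell mask."""
    tol = resolve_noise_tolerance(label_channel, cells_mask, params)
    return find_prominent_maxima(label_channel, cells_mask, tol,
                                 params.min_peak_value)


def delineate_clusters(label_channel: np.ndarray, peaks: np.ndarray,
                       params: ClusterParams, cells_mask: np.ndarray,
                       pixel_size_um: float):
    """Grow disjoint cluster footprints around the detected peaks.

    Each footprint is the connected set of in-cell pixels reachable from
    the peak with value >= peak − tolerance, truncated at
    ``max_footprint_radius_um``.  A contested pixel goes to the higher
    peak; between equal peaks to the nearer one; remaining ties break on
    the lexicographically smaller peak coordinate.  In maxima-only mode
    (``segmented=False``) footprints are the peak pixels themselves.

    Returns ``(cluster_mask, footprints)`` with one ``(rows, cols)`` pair
    per peak.
    """
    img = np.asarray(label_channel, dtype=float)
    h, w = img.shape
    cells_mask = np.asarray(cells_mask, dtype=bool)
    peaks = np.asarray(peaks, dtype=int).reshape(-1, 2)
    cluster_mask = np.zeros((h, w), dtype=bool)
    if peaks.shape[0] == 0:
        return cluster_mask, []
    if not params.segmented:
        footprints = []
        for pr, pc in peaks:
            cluster_mask[pr, pc] = True
            footprints.append((np.array([pr]), np.array([pc])))
        return cluster_mask, footprints

    tol = resolve_noise_tolerance(img, cells_mask, params)
    radius_px = params.max_footprint_radius_um / pixel_size_um
    r2max = radius_px * radius_px

    regions = []
    for k, (pr, pc) in enumerate(peaks):
        cut = img[pr, pc] - tol
        seen = {(int(pr), int(pc))}
        stack = [(int(pr), int(pc))]
        members = []
        while stack:
            r, c = stack.pop()
            members.append((r, c))
            for dr, dc in _NEIGHBORS:
                rr, cc = r + dr, c + dc
                if (0 <= rr < h and 0 <= cc < w and (rr, cc) not in seen
                        and cells_mask[rr, cc] and img[rr, cc] >= cut
                        and (rr - pr) ** 2 + (cc - pc) ** 2 <= r2max):
                    seen.add((rr, cc))
                    stack.append((rr, cc))
        regions.append(members)

    claims: dict[tuple, tuple] = {}
    owner: dict[tuple, int] = {}
    for k, (pr, pc) in enumerate(peaks):
        hgt = img[pr, pc]
        for r, c in regions[k]:
            d2 = (r - pr) ** 2 + (c - pc) ** 2
            key = (hgt, -d2, -pr, -pc)  # max-order: height, nearness, lex peak
            if (r, c) not in claims or key > claims[(r, c)]:
                claims[(r, c)] = key
                owner[(r, c)] = k
    for k, (pr, pc) in enumerate(peaks):  # a peak always owns its own pixel
        owner[(int(pr), int(pc))] = k

    footprints = []
    for k, (pr, pc) in enumerate(peaks):
        pix = [(r, c) for r, c in regions[k] if owner[(r, c)] == k]
        # keep only the part still connected to the peak after contention
        keep = {(int(pr), int(pc))}
        stack = [(int(pr), int(pc))]
        pixset = set(pix)
        while stack:
            r, c = stack.pop()
            for dr, dc in _NEIGHBORS:
                nb = (r + dr, c + dc)
                if nb in pixset and nb not in keep:
                    keep.add(nb)
                    stack.append(nb)
        arr = np.array(sorted(keep), dtype=int)
        rows, cols = arr[:, 0], arr[:, 1]
        footprints.append((rows, cols))
        cluster_mask[rows, cols] = True
    return cluster_mask, footprints


def classify_clusters(label_channel: np.ndarray, peaks: np.ndarray,
                      footprints: list, mask_set: MaskSet,
                      background: dict) -> list:
    """Assign each cluster the (population, surface) of its center pixel
    and compute background-corrected intensities.

    Clusters whose center falls outside ``cells_all`` are dropped with a
    logged warning.  ``background`` maps surface -> mean cell-free
    intensity on that surface (see :mod:`stripecluster.quantify`).
    """
    img = np.asarray(label_channel, dtype=float)
    records = []
    n_dropped = 0
    for (pr, pc), (rows, cols) in zip(np.asarray(peaks, int).reshape(-1, 2),
                                      footprints):
        population = None
        surface = None
        for (pop, surf), m in mask_set.combos.items():
            if m[pr, pc]:
                population, surface = pop, surf
                break
        if population is None or population == "none":
            n_dropped += 1
            continue
        bg = background[surface]
        peak_value = float(img[pr, pc])
        records.append(ClusterRecord(
            center=(int(pr), int(pc)), peak_value=peak_value,
            rows=rows, cols=cols,
            mean_pixel_intensity_bgcorr=float(img[rows, cols].mean() - bg),
            peak_value_bgcorr=peak_value - bg,
            population=population, surface=surface))
    if n_dropped:
        logger.warning("dropped %d cluster(s) with center on background",
                       n_dropped)
    return records


def cluster_table(records: list, image_id: str, pixel_size_um: float):
    """Tidy cluster table: one row per detected cluster."""
    rows = []
    for rec in records:
        rows.append({
            "image_id": image_id,
            "center_row": rec.center[0], "center_col": rec.center[1],
            "peak_value": rec.peak_value,
            "peak_value_bgcorr": rec.peak_value_bgcorr,
            "mean_pixel_intensity_bgcorr": rec.mean_pixel_intensity_bgcorr,
            "footprint_area_um2": rec.n_pixels * pixel_size_um ** 2,
            "population": rec.population, "surface": rec.surface,
        })
    return pd.DataFrame(rows, columns=[
        "image_id", "center_row", "center_col", "peak_value",
        "peak_value_bgcorr", "mean_pixel_intensity_bgcorr",
        "footprint_area_um2", "population", "surface"])
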