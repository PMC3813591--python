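"""Synthetic micropatterned immunofluorescence fields with planted truth.

The generator emulates a single confocal slice at the cell-glass contact
plane: alternating stripes of two stimuli (visualized in a stripe channel),
two co-seeded cell populations spreading with a configurable preference for
the stamped stripe class, Poisson-distributed diffraction-limited signaling
clusters whose density and amplitude depend on (population, surface), a
diffuse in-cell signal, a camera offset, and Gaussian (optionally
signal-proportional) noise.  Everything that is rendered is also reported as
:class:`~stripecluster.datatypes.GroundTruth`, so downstream stages can be
tested against exact planted values.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .datatypes import CellTruth, ClusterTruth, GroundTruth, ImageSet
from .errors import FrameTooCrowdedError
from .params import COMBOS, SceneParams

_EIGHT = np.ones((3, 3), dtype=bool)
#: rejection-sampling budget per cell before declaring the frame too crowded
MAX_PLACEMENT_ATTEMPTS = 500


def _stripe_phase(shape, period: int, orientation_deg: float) -> np.ndarray:
    """Coordinate along the stripe normal, wrapped to [0, period)."""
    rows, cols = np.mgrid[0: shape[0], 0: shape[1]]
    theta = math.radians(orientation_deg)
    # stripes run along direction (cos t, sin t) in (x, y); the normal
    # coordinate is u = -x sin t + y cos t.  orientation 0 -> u = row.
    u = rows * math.cos(theta) - cols * math.sin(theta)
    return np.mod(u, period)


def make_stripe_field(params: SceneParams, rng=None):
    """Render the stripe channel and its noiseless stamped mask.

    Returns ``(channel, stamped_mask)`` where stamped pixels have expected
    value ``stamp_level`` and overlay pixels ``overlay_level``.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    phase = _stripe_phase(params.frame_size_px, params.stripe_period_px,
                          params.stripe_orientation_deg)
    stamped = phase < params.stripe_fraction_stamped * params.stripe_period_px
    clean = np.where(stamped, params.stamp_level, params.overlay_level).astype(float)
    return _add_noise(clean, params, rng), stamped


def _add_noise(clean: np.ndarray, params: SceneParams, rng) -> np.ndarray:
    out = clean.copy()
    if params.noise_gaussian_sd > 0:
        out += rng.normal(0.0, params.noise_gaussian_sd, clean.shape)
    if params.noise_poisson_scale > 0:
        out += rng.standard_normal(clean.shape) * np.sqrt(
            params.noise_poisson_scale * np.clip(clean, 0, None))
    return np.clip(out, 0.0, None)


def _sample_footprint(params: SceneParams, stamped_mask, rng):
    """Draw one candidate cell footprint (pixel rows/cols and center).

    The footprint starts from an ellipse of area ~pi r².  When
    surface_preference != 1 the part on the non-preferred stripe class is
    shrunk by 1/preference *along the stripe direction*: every
    stripe-parallel chord lies in a single stripe class, so scaling the
    non-preferred chords realizes the commanded odds ratio of cell pixels
    on the stamped class exactly, and the footprint stays connected
    (the shrunk region spans the ellipse's full extent across the stripes).
    """
    h, w = params.frame_size_px
    mean_r, sd_r = params.cell_radius_um
    r_um = rng.normal(mean_r, sd_r)
    r_um = min(max(r_um, 0.25 * mean_r), 2.0 * mean_r)
    r_px = r_um / params.pixel_size_um
    axis_ratio = rng.uniform(1.0, 3.0)
    a = r_px * math.sqrt(axis_ratio)   # semi-axis along the phi direction
    b = r_px / math.sqrt(axis_ratio)
    theta = math.radians(params.stripe_orientation_deg)
    if params.elongate_along_stripes and params.surface_preference != 1.0:
        phi = theta  # long axis along the stripe direction
    else:
        phi = rng.uniform(0.0, math.pi)
    # cells may touch the frame edge, as in real fields of view, but a
    # footprint clipped below 60% of its nominal area is rejected.  With an
    # active preference, clipping is only allowed across the stripes:
    # cutting whole stripe-parallel chords is phase-uniform and leaves the
    # commanded odds ratio unbiased, whereas cutting chords lengthwise
    # would clip the full-length preferred chords more than the shrunk
    # non-preferred ones.
    h_row = math.hypot(a * math.sin(phi), b * math.cos(phi))
    h_col = math.hypot(a * math.cos(phi), b * math.sin(phi))
    s = params.surface_preference
    lo_r, hi_r, lo_c, hi_c = 0.0, h - 1.0, 0.0, w - 1.0
    if s != 1.0:
        t_mod = params.stripe_orientation_deg % 180.0
        if abs(t_mod) < 1e-9 or abs(t_mod - 180.0) < 1e-9:
            lo_c, hi_c = h_col, w - 1.0 - h_col   # horizontal stripes
        elif abs(t_mod - 90.0) < 1e-9:
            lo_r, hi_r = h_row, h - 1.0 - h_row   # vertical stripes
        else:                                     # oblique: no clipping
            lo_r, hi_r = h_row, h - 1.0 - h_row
            lo_c, hi_c = h_col, w - 1.0 - h_col
    if lo_r >= hi_r or lo_c >= hi_c:
        return None
    cy = rng.uniform(lo_r, hi_r)
    cx = rng.uniform(lo_c, hi_c)

    half = int(math.ceil(a)) + 1
    r0, r1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    c0, c1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - cy
    dx = xx - cx
    # stripe direction t = (sin th, cos th), normal n = (cos th, -sin th)
    # in (row, col) coordinates; u along stripes, v across them
    u = dy * math.sin(theta) + dx * math.cos(theta)
    v = dy * math.cos(theta) - dx * math.sin(theta)

    def inside(scale_u):
        du = u * scale_u
        py = du * math.sin(theta) + v * math.cos(theta)
        px = du * math.cos(theta) - v * math.sin(theta)
        e1 = (py * math.sin(phi) + px * math.cos(phi)) / a
        e2 = (py * math.cos(phi) - px * math.sin(phi)) / b
        return e1 * e1 + e2 * e2 <= 1.0

    full = inside(1.0)
    if full.sum() < 0.6 * math.pi * a * b:
        return None
    if s == 1.0:
        fp = full
    else:
        on_stamped = stamped_mask[r0:r1, c0:c1]
        if s > 1.0:  # overlay chords shrunk by 1/s
            fp = (full & on_stamped) | (inside(s) & ~on_stamped)
        else:        # stamped chords shrunk by s
            fp = (inside(1.0 / s) & on_stamped) | (full & ~on_stamped)
        # discretization safety: keep the piece connected to the center
        lab, _ = ndimage.label(fp, structure=_EIGHT)
        center_lab = lab[min(max(int(round(cy)) - r0, 0), lab.shape[0] - 1),
                         min(max(int(round(cx)) - c0, 0), lab.shape[1] - 1)]
        if center_lab == 0:
            return None
        fp = lab == center_lab
    rr, cc = np.nonzero(fp)
    return rr + r0, cc + c0, (cy, cx)


def place_cells(params: SceneParams, stamped_mask: np.ndarray, rng=None):
    """Place non-overlapping cell footprints and assign populations.

    Footprints are kept at least one pixel apart so that connected-component
    cell counting recovers the planted count.  Raises
    :class:`FrameTooCrowdedError` when a cell cannot be placed within the
    rejection budget.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    h, w = params.frame_size_px
    occupied_dil = np.zeros((h, w), dtype=bool)
    px_area = params.pixel_size_um ** 2
    cells = []
    for cell_id in range(params.n_cells):
        placed = False
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            cand = _sample_footprint(params, stamped_mask, rng)
            if cand is None:
                continue
            rr, cc, center = cand
            if occupied_dil[rr, cc].any():
                continue
            population = "labeled" if rng.random() < params.fraction_labeled \
                else "unlabeled"
            on_stamped = stamped_mask[rr, cc]
            cells.append(CellTruth(
                cell_id=cell_id, population=population, rows=rr, cols=cc,
                center=center,
                area_stamped_um2=float(on_stamped.sum()) * px_area,
                area_overlay_um2=float((~on_stamped).sum()) * px_area))
            fp = np.zeros((h, w), dtype=bool)
            fp[rr, cc] = True
            occupied_dil |= ndimage.binary_dilation(fp, structure=_EIGHT)
            placed = True
            break
        if not placed:
            raise FrameTooCrowdedError(
                f"frame too crowded: could not place cell {cell_id} after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts")
    return cells


def _sample_clusters(params: SceneParams, cells, stamped_mask, rng):
    clusters = []
    for cell in cells:
        on_stamped = stamped_mask[cell.rows, cell.cols]
        for surface, sel in (("stamped", on_stamped), ("overlay", ~on_stamped)):
            area_um2 = float(sel.sum()) * params.pixel_size_um ** 2
            rate = params.cluster_density_per_100um2.get(
                (cell.population, surface), 0.0)
            lam = rate * area_um2 / 100.0
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n == 0:
                continue
            idx = np.nonzero(sel)[0]
            picks = rng.choice(idx, size=n, replace=True)
            mean_a, sd_a = params.cluster_amplitude.get(
                (cell.population, surface), (0.0, 0.0))
            amps = np.clip(rng.normal(mean_a, sd_a, size=n), 0.0, None)
            for k in range(n):
                clusters.append(ClusterTruth(
                    cell_id=cell.cell_id,
                    center=(int(cell.rows[picks[k]]), int(cell.cols[picks[k]])),
                    amplitude=float(amps[k]),
                    population=cell.population, surface=surface))
    return clusters


def _render_spots(shape, clusters, sigma_px: float) -> np.ndarray:
    out = np.zeros(shape, dtype=float)
    if not clusters:
        return out
    half = max(1, int(math.ceil(4.0 * sigma_px)))
    span = np.arange(-half, half + 1)
    yy, xx = np.meshgrid(span, span, indexing="ij")
    kernel = np.exp(-(yy ** 2 + xx ** 2) / (2.0 * sigma_px ** 2))
    h, w = shape
    for cl in clusters:
        r, c = cl.center
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        c0, c1 = max(0, c - half), min(w, c + half + 1)
        out[r0:r1, c0:c1] += cl.amplitude * kernel[
            r0 - (r - half): r1 - (r - half),
            c0 - (c - half): c1 - (c - half)]
    return out


def render_image_set(params: SceneParams):
    """Render one field of view; returns ``(ImageSet, GroundTruth)``.

    Deterministic given ``params`` (including the seed): the same call
    yields bit-identical channels and truth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    stripe_channel, stamped_mask = make_stripe_field(params, rng)
    cells = place_cells(params, stamped_mask, rng)
    clusters = _sample_clusters(params, cells, stamped_mask, rng)

    shape = tuple(params.frame_size_px)
    label_clean = np.full(shape, params.label_offset, dtype=float)
    for cell in cells:
        label_clean[cell.rows, cell.cols] += \
            params.cell_background_level.get(cell.population, 0.0)
    sigma_px = params.cluster_sigma_um / params.pixel_size_um
    label_clean += _render_spots(shape, clusters, sigma_px)
    label_channel = _add_noise(label_clean, params, rng)

    tracer_clean = np.zeros(shape, dtype=float)
    for cell in cells:
        if cell.population == "labeled":
            tracer_clean[cell.rows, cell.cols] = params.tracer_level
    tracer_channel = np.clip(_add_noise(tracer_clean, params, rng),
                             0.0, params.tracer_clip)

    image_set = ImageSet(
        stripe_channel=stripe_channel, label_channel=label_channel,
        tracer_channel=tracer_channel, pixel_size_um=params.pixel_size_um,
        image_id=f"synthetic_{params.seed}",
        stamped_stimulus=params.stamped_stimulus,
        overlay_stimulus=params.overlay_stimulus,
        labeled_strain=params.labeled_strain,
        unlabeled_strain=params.unlabeled_strain)
    truth = GroundTruth(cells=cells, clusters=clusters,
                        stamped_mask=stamped_mask,
                        pixel_size_um=params.pixel_size_um, seed=params.seed)
    return image_set, truth


def expected_on_stamped_fraction(preference: float, stamped_fraction: float) -> float:
    """Closed-form expected fraction of cell pixels on the stamped class:
    s·f / (s·f + (1 - f)) for preference s and stamped area fraction f."""
    return (preference * stamped_fraction /
            (preference * stamped_fraction + (1.0 - stamped_fraction)))
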