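"""Per-(image, population, surface) quantification.

Computes, for each of the four cell combos of a field of view: covered
area, integrated and background-corrected mean intensity, cluster counts
and densities, and the per-population per-cell metrics (clusters per cell,
background-corrected integrated intensity per cell, contact area per
cell) together with the surface-preference score.

Background correction is surface-specific: the mean immunolabel intensity
of cell-free pixels on each stripe class is subtracted from per-pixel mean
intensities on that class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ImageSet, MaskSet
from .errors import EmptyBackgroundError
from .params import POPULATIONS, SURFACES


def estimate_background(label_channel: np.ndarray, mask_set: MaskSet) -> dict:
    """Mean immunolabel intensity of cell-free pixels per stripe class.

    Raises :class:`EmptyBackgroundError` when a stripe class has no
    cell-free pixels; in that case supply a fallback constant instead.
    """
    img = np.asarray(label_channel, dtype=float)
    out = {}
    for surface in SURFACES:
        region = mask_set.combo("none", surface)
        n = int(region.sum())
        if n == 0:
            raise EmptyBackgroundError(
                f"no cell-free pixels on the {surface} surface; "
                "pass a fallback background constant")
        out[surface] = float(img[region].mean())
    return out


def surface_preference_score(area_cell_on_a: float, area_cell_on_b: float,
                             total_area_a: float, total_area_b: float) -> float:
    """Spreading preference for surface A:
    (cell area on A / cell area on B) ÷ (total area A / total area B).

    1 means no preference, > 1 a preference for A.  Zero B-areas or total
    areas are rejected (the ratio is undefined).
    """
    if area_cell_on_b <= 0 or total_area_a <= 0 or total_area_b <= 0:
        raise ValueError("surface-preference score requires positive "
                         "denominator areas")
    if area_cell_on_a < 0:
        raise ValueError("areas must be nonnegative")
    return (area_cell_on_a / area_cell_on_b) / (total_area_a / total_area_b)


def measure_combos(image_set: ImageSet, mask_set: MaskSet, records: list,
                   background: dict, cell_counts: dict):
    """Measure the four cell combos and the per-population metrics.

    Returns ``(combo_df, population_df)``:

    * ``combo_df`` — one row per (population, surface): area (µm²), raw
      integrated intensity, background-corrected mean intensity per pixel,
      cluster count, clusters per 100 µm², mean background-corrected
      cluster-pixel intensity, plus the per-cell fields of its population.
    * ``population_df`` — one row per population: cell count, clusters per
      cell (both surfaces pooled), background-corrected integrated
      intensity per cell, contact area per cell, and the stamped-surface
      preference score.

    Densities and per-cell rates are reported as NaN (missing) when the
    respective denominator is zero.
    """
    img = np.asarray(image_set.label_channel, dtype=float)
    px = image_set.pixel_size_um
    px_area = px * px

    per_combo = {}
    for pop in POPULATIONS:
        for surf in SURFACES:
            m = mask_set.combo(pop, surf)
            n_px = int(m.sum())
            integrated = float(img[m].sum())
            combo_records = [r for r in records
                             if r.population == pop and r.surface == surf]
            n_cl = len(combo_records)
            per_combo[(pop, surf)] = {
                "n_px": n_px,
                "area_um2": n_px * px_area,
                "integrated_intensity": integrated,
                "mean_intensity_bgcorr": (integrated / n_px - background[surf])
                if n_px > 0 else np.nan,
                "cluster_count": n_cl,
                "clusters_per_100um2": (100.0 * n_cl / (n_px * px_area))
                if n_px > 0 else np.nan,
                "mean_cluster_intensity_bgcorr": float(np.mean(
                    [r.mean_pixel_intensity_bgcorr for r in combo_records]))
                if n_cl > 0 else np.nan,
                "mean_cluster_peak_bgcorr": float(np.mean(
                    [r.peak_value_bgcorr for r in combo_records]))
                if n_cl > 0 else np.nan,
            }

    total_area = {s: float(mask_set.surface_mask(s).sum()) * px_area
                  for s in SURFACES}

    pop_rows = []
    for pop in POPULATIONS:
        stamped = per_combo[(pop, "stamped")]
        overlay = per_combo[(pop, "overlay")]
        n_cells = cell_counts.get(pop, 0)
        n_cl = stamped["cluster_count"] + overlay["cluster_count"]
        bgcorr_int = sum(
            c["integrated_intensity"] - background[s] * c["n_px"]
            for s, c in (("stamped", stamped), ("overlay", overlay)))
        area = stamped["area_um2"] + overlay["area_um2"]
        if overlay["area_um2"] > 0:
            sps = surface_preference_score(
                stamped["area_um2"], overlay["area_um2"],
                total_area["stamped"], total_area["overlay"])
        else:
            sps = np.nan
        pop_rows.append({
            "image_id": image_set.image_id,
            "population": pop,
            "strain": image_set.strain_of(pop),
            "stamped_stimulus": image_set.stamped_stimulus,
            "overlay_stimulus": image_set.overlay_stimulus,
            "cell_count": n_cells,
            "clusters_per_cell": n_cl / n_cells if n_cells > 0 else np.nan,
            "intensity_per_cell": bgcorr_int / n_cells if n_cells > 0 else np.nan,
            "area_per_cell_um2": area / n_cells if n_cells > 0 else np.nan,
            "sps_stamped": sps,
        })
    population_df = pd.DataFrame(pop_rows)

    combo_rows = []
    for pop in POPULATIONS:
        pop_row = population_df[population_df["population"] == pop].iloc[0]
        for surf in SURFACES:
            c = per_combo[(pop, surf)]
            combo_rows.append({
                "image_id": image_set.image_id,
                "population": pop, "surface": surf,
                "strain": image_set.strain_of(pop),
                "stimulus": image_set.stimulus_of(surf),
                "area_um2": c["area_um2"],
                "integrated_intensity": c["integrated_intensity"],
                "mean_intensity_bgcorr": c["mean_intensity_bgcorr"],
                "cluster_count": c["cluster_count"],
                "clusters_per_100um2": c["clusters_per_100um2"],
                "mean_cluster_intensity_bgcorr": c["mean_cluster_intensity_bgcorr"],
                "mean_cluster_peak_bgcorr": c["mean_cluster_peak_bgcorr"],
                "cell_count": pop_row["cell_count"],
                "clusters_per_cell": pop_row["clusters_per_cell"],
                "intensity_per_cell": pop_row["intensity_per_cell"],
            })
    combo_df = pd.DataFrame(combo_rows)
    return combo_df, population_df
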