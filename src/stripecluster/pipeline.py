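"""End-to-end orchestration: simulate or load image sets, segment, detect
clusters, quantify, pool and test — with every intermediate written out.

Per-image processing follows the mask-algebra flow: threshold the stripe
channel into stamped/overlay, the immunolabel channel into cells/background
and the tracer channel into labeled/unlabeled; intersect into the six-way
mask set; estimate per-surface cell-free background; detect and classify
microclusters; measure the per-combo and per-population quantities.
Across images, measurements are mapped from (population, surface) to the
experimental factors (strain, stimulus) via each image's metadata — which
is what makes datasets with swapped tracer assignment or swapped
stamp/overlay orientation poolable — normalized within image, and analyzed
with the two-factor ANOVA and t tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from . import clusters as clmod
from . import quantify, segmentation, stats, synthgen
from .datatypes import ImageSet, MaskSet
from .errors import StripeClusterError
from .params import RunConfig, SceneParams

logger = logging.getLogger(__name__)

#: properties analyzed with the 2x2 (strain x stimulus) ANOVA
ANOVA_PROPERTIES = ("mean_intensity_bgcorr", "mean_cluster_intensity_bgcorr",
                    "clusters_per_100um2")
#: per-population properties compared between strains with two-sample t tests
PERCELL_PROPERTIES = ("clusters_per_cell", "intensity_per_cell",
                      "area_per_cell_um2")


class EmptyDatasetError(StripeClusterError):
    """No input images were found."""


class UnreadableImageError(StripeClusterError):
    """A TIFF file or its metadata sidecar could not be read."""


def simulate_dataset(config: RunConfig):
    """Generate ``config.n_images`` image sets from ``config.scene``.

    Per-image seeds are spawned deterministically from ``config.seed``.
    With ``vary_configurations`` the four combinations of swapped
    stamp/overlay stimulus and swapped tracer assignment are cycled across
    images, mirroring the pooled experimental design; the generator maps
    are permuted consistently so the (strain, stimulus) ground truth is
    identical across configurations.
    """
    rng = np.random.default_rng(config.seed)
    image_seeds = rng.integers(0, 2 ** 31 - 1, size=config.n_images)
    out = []
    base = config.scene
    for i in range(config.n_images):
        scene = derive_scene(base, int(image_seeds[i]),
                             flip_surface=config.vary_configurations and bool(i & 1),
                             flip_label=config.vary_configurations and bool(i & 2))
        image_set, truth = synthgen.render_image_set(scene)
        image_set.image_id = f"img{i:03d}"
        out.append((image_set, truth))
    return out


def derive_scene(base: SceneParams, seed: int, flip_surface: bool = False,
                 flip_label: bool = False) -> SceneParams:
    """One image's scene: new seed, optionally with the stamped/overlaid
    stimuli or the tracer-labeled strain swapped (maps permuted so that the
    underlying (strain, stimulus) conditions are unchanged)."""
    scene = dataclasses.replace(base, seed=seed)
    if flip_surface:
        scene = dataclasses.replace(
            scene,
            stamped_stimulus=base.overlay_stimulus,
            overlay_stimulus=base.stamped_stimulus,
            stripe_fraction_stamped=1.0 - base.stripe_fraction_stamped,
            surface_preference=1.0 / base.surface_preference,
            cluster_density_per_100um2={
                (p, _flip_s(s)): v
                for (p, s), v in base.cluster_density_per_100um2.items()},
            cluster_amplitude={
                (p, _flip_s(s)): v
                for (p, s), v in base.cluster_amplitude.items()})
    if flip_label:
        scene = dataclasses.replace(
            scene,
            labeled_strain=scene.unlabeled_strain,
            unlabeled_strain=scene.labeled_strain,
            fraction_labeled=1.0 - scene.fraction_labeled,
            cluster_density_per_100um2={
                (_flip_p(p), s): v
                for (p, s), v in scene.cluster_density_per_100um2.items()},
            cluster_amplitude={
                (_flip_p(p), s): v
                for (p, s), v in scene.cluster_amplitude.items()},
            cell_background_level={
                _flip_p(p): v
                for p, v in scene.cell_background_level.items()})
    return scene


def _flip_s(surface: str) -> str:
    return "overlay" if surface == "stamped" else "stamped"


def _flip_p(population: str) -> str:
    return "unlabeled" if population == "labeled" else "labeled"


def load_dataset(input_dir) -> list:
    """Read ``*_img.tif`` image sets (with YAML sidecars) from a directory."""
    input_dir = Path(input_dir)
    paths = sorted(input_dir.glob("*_img.tif"))
    if not paths:
        raise EmptyDatasetError(f"no *_img.tif files in {input_dir}")
    out = []
    for p in paths:
        try:
            out.append((ImageSet.read(p), None))
        except Exception as exc:  # pragma: no cover - depends on input
            raise UnreadableImageError(f"could not read {p}: {exc}") from exc
    return out


def segment_image(image_set: ImageSet, config: RunConfig):
    """Build the six-way mask set for one image; returns
    ``(mask_set, thresholds_used)``."""
    th = config.thresholds
    stripe_thr = segmentation.compute_threshold(
        image_set.stripe_channel, th.stripe_method, th.stripe_value)
    stripe_mask = image_set.stripe_channel > stripe_thr
    cell_thr = segmentation.compute_threshold(
        image_set.label_channel, th.cell_method, th.cell_value)
    cell_mask = segmentation.threshold_mask(
        image_set.label_channel, "fixed", cell_thr,
        min_object_px=th.min_object_px, fill_holes=th.fill_holes)
    tracer_mask = None
    tracer_thr = None
    if image_set.tracer_channel is not None:
        tracer_thr = segmentation.compute_threshold(
            image_set.tracer_channel, th.tracer_method, th.tracer_value)
        tracer_mask = segmentation.threshold_mask(
            image_set.tracer_channel, "fixed", tracer_thr,
            min_object_px=th.min_object_px, fill_holes=th.fill_holes)
    mask_set = segmentation.build_mask_set(stripe_mask, cell_mask, tracer_mask)
    thresholds = {"stripe": stripe_thr, "cell": cell_thr, "tracer": tracer_thr}
    logger.info("image %s thresholds: %s", image_set.image_id, thresholds)
    return mask_set, thresholds


def process_image(image_set: ImageSet, config: RunConfig) -> dict:
    """Run segmentation, cluster detection and quantification for one
    image; returns all per-image artifacts in a dict."""
    mask_set, thresholds = segment_image(image_set, config)
    background = quantify.estimate_background(image_set.label_channel, mask_set)
    peaks = clmod.detect_maxima(image_set.label_channel, mask_set.cells_all,
                                config.cluster)
    _, footprints = clmod.delineate_clusters(
        image_set.label_channel, peaks, config.cluster, mask_set.cells_all,
        image_set.pixel_size_um)
    records = clmod.classify_clusters(image_set.label_channel, peaks,
                                      footprints, mask_set, background)
    cell_counts = segmentation.count_cells(
        {"labeled": mask_set.cells_labeled,
         "unlabeled": mask_set.cells_unlabeled},
        config.thresholds.min_cell_area_um2, image_set.pixel_size_um)
    combo_df, population_df = quantify.measure_combos(
        image_set, mask_set, records, background, cell_counts)
    return {"mask_set": mask_set, "thresholds": thresholds,
            "background": background, "peaks": peaks, "records": records,
            "combo_df": combo_df, "population_df": population_df,
            "cluster_df": clmod.cluster_table(records, image_set.image_id,
                                              image_set.pixel_size_um)}


def combos_to_long(combo_df: pd.DataFrame) -> pd.DataFrame:
    """Melt the per-combo table into tidy (image, strain, stimulus,
    property, value) rows for the statistics layer."""
    keep = ["image_id", "strain", "stimulus"]
    long = combo_df.melt(id_vars=keep, value_vars=list(ANOVA_PROPERTIES),
                         var_name="property", value_name="value")
    return long


def percell_to_long(population_df: pd.DataFrame) -> pd.DataFrame:
    keep = ["image_id", "strain"]
    long = population_df.melt(id_vars=keep, value_vars=list(PERCELL_PROPERTIES),
                              var_name="property", value_name="value")
    return long


def analyze(combo_all: pd.DataFrame, population_all: pd.DataFrame,
            config: RunConfig):
    """Pool per-image measurements and run the statistics layer.

    Returns ``(effects_df, assumptions_df, ttests_df, normalized_df,
    population_df)`` where the population table gains a pooled,
    orientation-corrected SPS column.
    """
    long = combos_to_long(combo_all)
    normalized = stats.normalize_within_image(long)
    pooled = normalized[~normalized["excluded"]]

    assumption_frames = []
    anova_frames = []
    for prop in ANOVA_PROPERTIES:
        report = stats.check_assumptions(pooled, prop, alpha=config.alpha)
        assumption_frames.append(report.to_frame())
        result = stats.anova_effects(
            pooled, prop, include_interaction=config.include_interaction,
            block_by_image=config.block_by_image, alpha=config.alpha)
        anova_frames.append(result.to_frame())
    effects_df = pd.concat(anova_frames, ignore_index=True)
    assumptions_df = pd.concat(assumption_frames, ignore_index=True)

    # per-cell metrics: strain effect only, two-sample t on values
    # normalized within image across the two strains
    pc_long = percell_to_long(population_all)
    pc_norm = stats.normalize_within_image(pc_long)
    pc_pooled = pc_norm[~pc_norm["excluded"]]
    ttest_rows = []
    strains = sorted(population_all["strain"].unique())
    for prop in PERCELL_PROPERTIES:
        sub = pc_pooled[pc_pooled["property"] == prop].dropna(
            subset=["normalized"])
        groups = [sub[sub["strain"] == s]["normalized"].to_numpy()
                  for s in strains]
        if len(strains) == 2 and all(len(g) >= 2 for g in groups):
            res = stats.two_sample_t(groups[0], groups[1],
                                     equal_var=config.equal_var)
            ttest_rows.append({
                "property": prop, "test": "two_sample",
                "contrast": f"{strains[0]} - {strains[1]}",
                "statistic": res.statistic, "df": res.df,
                "p_value": res.p_value, "n": res.n, "mean_diff": res.mean})

    # surface-preference score vs 1 per strain, pooled over images.  The
    # score is reoriented to one reference stimulus so that images with
    # swapped stamp/overlay configurations pool consistently.
    ref = config.scene.stamped_stimulus if config.mode == "synthetic" \
        else str(population_all["stamped_stimulus"].iloc[0])
    sps_ref = np.where(population_all["stamped_stimulus"] == ref,
                       population_all["sps_stamped"],
                       1.0 / population_all["sps_stamped"])
    population_all = population_all.assign(**{f"sps_{ref}": sps_ref})
    for strain in strains:
        vals = population_all[population_all["strain"] == strain][
            f"sps_{ref}"].dropna().to_numpy()
        if len(vals) >= 2 and np.std(vals, ddof=1) > 0:
            res = stats.one_sample_t(vals, popmean=1.0)
            ttest_rows.append({
                "property": f"sps_{ref}", "test": "one_sample_vs_1",
                "contrast": strain, "statistic": res.statistic,
                "df": res.df, "p_value": res.p_value, "n": res.n,
                "mean_diff": res.mean})
    ttests_df = pd.DataFrame(ttest_rows)

    if config.bonferroni_family:
        adj, sig = stats.bonferroni_adjust(
            effects_df["p_value"].to_numpy(), config.bonferroni_family,
            alpha=config.alpha)
        effects_df["p_bonferroni"] = adj
        effects_df["significant"] = sig
    return effects_df, assumptions_df, ttests_df, normalized, population_all


def run(config: RunConfig) -> dict:
    """Execute an end-to-end run and (optionally) write all artifacts to
    ``config.output_dir``.  Deterministic given config + seed."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    if config.mode == "synthetic":
        dataset = simulate_dataset(config)
    else:
        dataset = load_dataset(config.input_dir)
    if not dataset:
        raise EmptyDatasetError("dataset is empty")

    per_image = []
    combo_frames, pop_frames, cluster_frames = [], [], []
    truths = []
    for image_set, truth in dataset:
        result = process_image(image_set, config)
        per_image.append((image_set, result))
        combo_frames.append(result["combo_df"])
        pop_frames.append(result["population_df"])
        cluster_frames.append(result["cluster_df"])
        truths.append(truth)
    combo_all = pd.concat(combo_frames, ignore_index=True)
    population_all = pd.concat(pop_frames, ignore_index=True)
    cluster_all = pd.concat(cluster_frames, ignore_index=True)

    effects_df, assumptions_df, ttests_df, normalized, population_all = \
        analyze(combo_all, population_all, config)

    bundle = {"combo": combo_all, "population": population_all,
              "clusters": cluster_all, "effects": effects_df,
              "assumptions": assumptions_df, "ttests": ttests_df,
              "normalized": normalized, "per_image": per_image,
              "truths": truths}

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        combo_all.to_csv(outdir / "combo_measurements.csv", index=False)
        population_all.to_csv(outdir / "population_measurements.csv",
                              index=False)
        cluster_all.to_csv(outdir / "cluster_table.csv", index=False)
        effects_df.to_csv(outdir / "effects.csv", index=False)
        assumptions_df.to_csv(outdir / "assumption_report.csv", index=False)
        ttests_df.to_csv(outdir / "t_tests.csv", index=False)
        normalized.to_csv(outdir / "normalized_records.csv", index=False)
        summary = {
            "n_images": len(per_image),
            "properties": list(ANOVA_PROPERTIES) + list(PERCELL_PROPERTIES),
            "thresholds": [
                {"image_id": im.image_id, **{k: (float(v) if v is not None
                                                 else None)
                                             for k, v in r["thresholds"].items()}}
                for im, r in per_image],
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        for image_set, result in per_image:
            mask_set: MaskSet = result["mask_set"]
            stack = np.stack([
                mask_set.stamped, mask_set.cells_all, mask_set.cells_labeled,
                mask_set.cells_unlabeled]).astype(np.uint8) * 255
            tifffile.imwrite(outdir / f"{image_set.image_id}_masks.tif",
                             stack, photometric="minisblack",
                             planarconfig="separate")
    return bundle


def demo(seed: int = 0, output_dir: Optional[str] = None) -> dict:
    """Miniature worked example: two small synthetic fields through the
    whole pipeline, returning a printable report with mask-partition
    checks, surface-preference scores and truth-vs-measured cluster
    counts."""
    scene = SceneParams(frame_size_px=(256, 256), n_cells=4,
                        cell_radius_um=(4.5, 0.5), stripe_period_px=24,
                        seed=seed)
    config = RunConfig(mode="synthetic", scene=scene, n_images=2,
                       vary_configurations=False, seed=seed,
                       output_dir=output_dir)
    bundle = run(config)

    lines = ["stripecluster demo", "=" * 40]
    for image_set, result in bundle["per_image"]:
        mask_set = result["mask_set"]
        areas = {f"{p}|{s}": int(m.sum()) for (p, s), m in
                 mask_set.combos.items()}
        frame = image_set.shape[0] * image_set.shape[1]
        lines.append(f"{image_set.image_id}: combo pixel areas {areas}; "
                     f"sum={sum(areas.values())} frame={frame}")
    truth_count = sum(len(t.clusters) for t in bundle["truths"] if t)
    measured_count = int(bundle["combo"]["cluster_count"].sum())
    lines.append(f"clusters: planted={truth_count} measured={measured_count}")
    sps_rows = bundle["ttests"][
        bundle["ttests"]["property"].str.startswith("sps_")]
    for _, row in sps_rows.iterrows():
        lines.append(
            f"SPS[{row['contrast']}] mean={row['mean_diff']:.3f} "
            f"t={row['statistic']:.2f} p={row['p_value']:.3g} (vs 1)")
    report = "\n".join(lines)
    return {"report": report, "bundle": bundle,
            "truth_clusters": truth_count, "measured_clusters": measured_count}
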