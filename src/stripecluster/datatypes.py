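"""Core data containers: image sets, mask sets, ground truth and records.

Conventions used throughout the package: 0-based (row, col) pixel indexing,
8-connectivity for connected components, and area = pixel count ×
pixel_size_um².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ShapeMismatchError
from .params import COMBOS, SceneParams

#: channel order of multi-page TIFF exports
CHANNEL_ORDER = ("stripe", "label", "tracer")


@dataclass
class ImageSet:
    """One field of view: the stripe-pattern channel, the immunolabel
    channel, an optional cell-tracer channel, plus physical and
    experimental metadata."""

    stripe_channel: np.ndarray
    label_channel: np.ndarray
    tracer_channel: Optional[np.ndarray]
    pixel_size_um: float
    image_id: str = "image"
    stamped_stimulus: str = "CD3+CD28"
    overlay_stimulus: str = "CD3"
    labeled_strain: str = "KD"
    unlabeled_strain: str = "wt"

    def __post_init__(self):
        shape = self.stripe_channel.shape
        for name in ("label_channel", "tracer_channel"):
            ch = getattr(self, name)
            if ch is not None and ch.shape != shape:
                raise ShapeMismatchError(
                    f"{name} shape {ch.shape} != stripe shape {shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        for name in ("stripe_channel", "label_channel", "tracer_channel"):
            ch = getattr(self, name)
            if ch is not None and np.any(ch < 0):
                raise ValueError(f"{name} must be nonnegative")

    @property
    def shape(self):
        return self.stripe_channel.shape

    def strain_of(self, population: str) -> str:
        return self.labeled_strain if population == "labeled" else self.unlabeled_strain

    def stimulus_of(self, surface: str) -> str:
        return self.stamped_stimulus if surface == "stamped" else self.overlay_stimulus

    # -- TIFF round trip ------------------------------------------------
    def write(self, path) -> None:
        """Write channels as a multi-page TIFF (page order stripe, label,
        tracer) and the metadata as a YAML sidecar ``<stem>.yaml``."""
        path = Path(path)
        tracer = self.tracer_channel
        pages = [self.stripe_channel, self.label_channel]
        if tracer is not None:
            pages.append(tracer)
        tifffile.imwrite(path, np.stack(pages).astype(np.float32),
                         photometric="minisblack", planarconfig="separate")
        meta = {
            "image_id": self.image_id,
            "pixel_size_um": float(self.pixel_size_um),
            "channels": list(CHANNEL_ORDER[: len(pages)]),
            "stamped_stimulus": self.stamped_stimulus,
            "overlay_stimulus": self.overlay_stimulus,
            "labeled_strain": self.labeled_strain,
            "unlabeled_strain": self.unlabeled_strain,
        }
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)

    @classmethod
    def read(cls, path) -> "ImageSet":
        path = Path(path)
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        with open(path.with_suffix(".yaml")) as fh:
            meta = yaml.safe_load(fh)
        channels = meta.get("channels", list(CHANNEL_ORDER[: len(stack)]))
        by_name = {name: np.asarray(stack[i], dtype=np.float64)
                   for i, name in enumerate(channels)}
        return cls(
            stripe_channel=by_name["stripe"],
            label_channel=by_name["label"],
            tracer_channel=by_name.get("tracer"),
            pixel_size_um=float(meta["pixel_size_um"]),
            image_id=str(meta.get("image_id", path.stem)),
            stamped_stimulus=meta.get("stamped_stimulus", "CD3+CD28"),
            overlay_stimulus=meta.get("overlay_stimulus", "CD3"),
            labeled_strain=meta.get("labeled_strain", "KD"),
            unlabeled_strain=meta.get("unlabeled_strain", "wt"),
        )


@dataclass
class MaskSet:
    """The six-way binary decomposition of one field of view.

    ``stamped``/``overlay`` partition the frame by stripe class;
    ``cells_labeled``/``cells_unlabeled`` partition ``cells_all`` by
    population; ``background`` is the complement of ``cells_all``.  The six
    ``combos`` — (population ∈ {labeled, unlabeled, none}, surface) — are
    the pairwise intersections and partition the frame exactly.
    """

    stamped: np.ndarray
    overlay: np.ndarray
    cells_all: np.ndarray
    cells_labeled: np.ndarray
    cells_unlabeled: np.ndarray
    background: np.ndarray
    combos: dict = field(default_factory=dict)

    POPULATION_ROWS = ("labeled", "unlabeled", "none")

    def combo(self, population: str, surface: str) -> np.ndarray:
        return self.combos[(population, surface)]

    def surface_mask(self, surface: str) -> np.ndarray:
        return self.stamped if surface == "stamped" else self.overlay

    def validate(self) -> None:
        shape = self.stamped.shape
        masks = [self.overlay, self.cells_all, self.cells_labeled,
                 self.cells_unlabeled, self.background]
        if any(m.shape != shape for m in masks):
            raise ShapeMismatchError("mask shapes differ")
        assert not np.any(self.stamped & self.overlay)
        assert np.all(self.stamped | self.overlay)
        assert not np.any(self.cells_labeled & self.cells_unlabeled)
        assert np.array_equal(self.cells_labeled | self.cells_unlabeled,
                              self.cells_all)
        assert np.array_equal(self.background, ~self.cells_all)
        total = np.zeros(shape, dtype=np.int64)
        for (pop, surf), m in self.combos.items():
            parent = {"labeled": self.cells_labeled,
                      "unlabeled": self.cells_unlabeled,
                      "none": self.background}[pop]
            assert np.array_equal(m, parent & self.surface_mask(surf))
            total += m
        assert np.all(total == 1), "combos must partition the frame"

    def area_summary(self, pixel_size_um: float) -> pd.DataFrame:
        """Per-mask pixel counts, areas (µm²) and frame fractions (QC)."""
        rows = []
        n_frame = self.stamped.size
        named = {"stamped": self.stamped, "overlay": self.overlay,
                 "cells_all": self.cells_all, "cells_labeled": self.cells_labeled,
                 "cells_unlabeled": self.cells_unlabeled,
                 "background": self.background}
        named.update({f"{p}|{s}": m for (p, s), m in self.combos.items()})
        for name, m in named.items():
            n = int(m.sum())
            rows.append({"mask": name, "pixels": n,
                         "area_um2": n * pixel_size_um ** 2,
                         "frame_fraction": n / n_frame})
        return pd.DataFrame(rows)


@dataclass
class CellTruth:
    """Ground truth for one synthetic cell."""

    cell_id: int
    population: str
    rows: np.ndarray
    cols: np.ndarray
    center: tuple
    area_stamped_um2: float
    area_overlay_um2: float

    @property
    def area_um2(self) -> float:
        return self.area_stamped_um2 + self.area_overlay_um2


@dataclass
class ClusterTruth:
    """Ground truth for one planted microcluster."""

    cell_id: int
    center: tuple
    amplitude: float
    population: str
    surface: str


@dataclass
class GroundTruth:
    """Exhaustive ground truth of one rendered field of view."""

    cells: list
    clusters: list
    stamped_mask: np.ndarray
    pixel_size_um: float
    seed: int

    def combo_cluster_counts(self) -> dict:
        counts = {combo: 0 for combo in COMBOS}
        for cl in self.clusters:
            counts[(cl.population, cl.surface)] += 1
        return counts

    def combo_mean_amplitudes(self) -> dict:
        sums = {combo: [] for combo in COMBOS}
        for cl in self.clusters:
            sums[(cl.population, cl.surface)].append(cl.amplitude)
        return {c: (float(np.mean(v)) if v else np.nan) for c, v in sums.items()}

    def combo_areas_um2(self) -> dict:
        areas = {combo: 0.0 for combo in COMBOS}
        for cell in self.cells:
            areas[(cell.population, "stamped")] += cell.area_stamped_um2
            areas[(cell.population, "overlay")] += cell.area_overlay_um2
        return areas

    def cell_counts(self) -> dict:
        out = {"labeled": 0, "unlabeled": 0}
        for cell in self.cells:
            out[cell.population] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy truth table: one row per cell and one per cluster."""
        rows = []
        for cell in self.cells:
            rows.append({"record": "cell", "cell_id": cell.cell_id,
                         "population": cell.population, "surface": "",
                         "row": cell.center[0], "col": cell.center[1],
                         "area_stamped_um2": cell.area_stamped_um2,
                         "area_overlay_um2": cell.area_overlay_um2,
                         "amplitude": np.nan})
        for cl in self.clusters:
            rows.append({"record": "cluster", "cell_id": cl.cell_id,
                         "population": cl.population, "surface": cl.surface,
                         "row": cl.center[0], "col": cl.center[1],
                         "area_stamped_um2": np.nan, "area_overlay_um2": np.nan,
                         "amplitude": cl.amplitude})
        return pd.DataFrame(rows)


@dataclass
class ClusterRecord:
    """One detected microcluster, classified by (population, surface)."""

    center: tuple
    peak_value: float
    rows: np.ndarray
    cols: np.ndarray
    mean_pixel_intensity_bgcorr: float
    peak_value_bgcorr: float
    population: str
    surface: str

    @property
    def n_pixels(self) -> int:
        return len(self.rows)


def write_image_set(image_set: ImageSet, truth: GroundTruth,
                    params: SceneParams, dataset_dir, image_id: str) -> None:
    """Write ``<dataset>/<image_id>_img.tif`` (+YAML sidecar),
    ``<image_id>_truth.csv`` and ``<image_id>_params.yaml``."""
    dataset_dir = Path(dataset_dir)
    dataset_dir.mkdir(parents=True, exist_ok=True)
    image_set.write(dataset_dir / f"{image_id}_img.tif")
    truth.to_frame().to_csv(dataset_dir / f"{image_id}_truth.csv", index=False)
    with open(dataset_dir / f"{image_id}_params.yaml", "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)
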