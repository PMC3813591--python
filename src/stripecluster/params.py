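"""Parameter containers for simulation, detection and pipeline runs.

All parameters carry physical units where applicable (lengths in µm,
intensities in arbitrary camera units, rates per 100 µm²).  The scene
parameters default to the experimental geometry of striped microcontact
printed stimuli imaged at 0.12 µm/px: two alternating stripe classes
("stamped" and "overlay"), two co-seeded Jurkat strains of which one is
tracer (CFSE) labeled, diffraction-limited signaling microclusters inside
the cell contact footprints, and a diffuse membrane-proximal signal on top
of a camera offset.

Default cluster densities per (population, surface) are set to the
magnitudes measured for phosphotyrosine microclusters in this system
(roughly 9-12 clusters per 100 µm², higher on the costimulatory surface).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

POPULATIONS = ("labeled", "unlabeled")
SURFACES = ("stamped", "overlay")
COMBOS = tuple((p, s) for p in POPULATIONS for s in SURFACES)


def _default_density() -> dict:
    # labeled strain = knock-down, stamped surface = costimulatory mix by default
    return {
        ("labeled", "stamped"): 11.7,
        ("labeled", "overlay"): 8.9,
        ("unlabeled", "stamped"): 11.4,
        ("unlabeled", "overlay"): 9.2,
    }


def _default_amplitude() -> dict:
    return {combo: (80.0, 20.0) for combo in COMBOS}


def _default_cell_background() -> dict:
    return {"labeled": 15.0, "unlabeled": 15.0}


@dataclass
class SceneParams:
    """Ground-truth parameters for one synthetic field of view.

    Attributes
    ----------
    frame_size_px : (int, int)
        Image shape (rows, cols).
    pixel_size_um : float
        Lateral sampling, default 0.12 µm.
    stripe_period_px, stripe_fraction_stamped, stripe_orientation_deg :
        Stripe geometry; orientation is the angle of the stripe direction
        relative to the image x axis (0 = horizontal stripes).
    stamp_level, overlay_level : float
        Mean stripe-channel intensity of the two stripe classes (a.u.).
    n_cells, fraction_labeled : cell seeding.
    cell_radius_um : (mean, sd)
        Effective radius of the contact footprint (area pi r²); the default
        mean of 7.3 µm gives ~170 µm² contact areas.
    surface_preference : float
        Odds multiplier that a cell pixel lands on the stamped stripe class;
        1 = indifferent.  Realized by shrinking the footprint on the
        non-preferred class (area factor 1/preference) so footprints stay
        connected.
    cluster_density_per_100um2 : {(population, surface): rate}
    cluster_amplitude : {(population, surface): (mean, sd)} spot peak
        amplitudes above the diffuse in-cell level (a.u.).
    cluster_sigma_um : float
        PSF-like Gaussian spot width (sd), default 0.15 µm.
    cell_background_level : {population: a.u.} diffuse in-cell signal.
    label_offset : float
        Camera/mounting offset present everywhere in the immunolabel channel;
        this is what surface-specific background correction removes.
    tracer_level, tracer_clip : float
        Tracer-channel intensity of labeled cells and the full-scale clip;
        the default level exceeds the clip so the channel saturates, as CFSE
        is typically recorded.
    noise_gaussian_sd, noise_poisson_scale : float
        Additive Gaussian read noise and optional signal-proportional
        variance term (var = scale × clean signal).
    elongate_along_stripes : bool
        If True and surface_preference != 1, cell ellipses are aligned with
        the stripe direction instead of randomly oriented.
    stamped_stimulus, overlay_stimulus, labeled_strain, unlabeled_strain :
        Metadata mapping image-level classes to experimental factors.
    seed : int
        Seed for the per-image random stream; identical params (including
        seed) give bit-identical renders.
    """

    frame_size_px: tuple = (512, 512)
    pixel_size_um: float = 0.12
    stripe_period_px: int = 40
    stripe_fraction_stamped: float = 0.5
    stripe_orientation_deg: float = 0.0
    stamp_level: float = 120.0
    overlay_level: float = 10.0
    n_cells: int = 8
    fraction_labeled: float = 0.5
    cell_radius_um: tuple = (7.3, 0.8)
    surface_preference: float = 1.5
    cluster_density_per_100um2: dict = field(default_factory=_default_density)
    cluster_amplitude: dict = field(default_factory=_default_amplitude)
    cluster_sigma_um: float = 0.15
    cell_background_level: dict = field(default_factory=_default_cell_background)
    label_offset: float = 10.0
    tracer_level: float = 300.0
    tracer_clip: float = 255.0
    noise_gaussian_sd: float = 3.0
    noise_poisson_scale: float = 0.0
    elongate_along_stripes: bool = False
    stamped_stimulus: str = "CD3+CD28"
    overlay_stimulus: str = "CD3"
    labeled_strain: str = "KD"
    unlabeled_strain: str = "wt"
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        h, w = self.frame_size_px
        if h < 1 or w < 1:
            raise ValueError("frame_size_px must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.stripe_period_px < 2:
            raise ValueError("stripe_period_px must be >= 2")
        if not 0.0 < self.stripe_fraction_stamped < 1.0:
            raise ValueError("stripe_fraction_stamped must lie in (0, 1)")
        if not 0.0 <= self.fraction_labeled <= 1.0:
            raise ValueError("fraction_labeled must lie in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.surface_preference <= 0:
            raise ValueError("surface_preference must be > 0")
        if self.cluster_sigma_um <= 0:
            raise ValueError("cluster_sigma_um must be > 0")
        if self.noise_gaussian_sd < 0 or self.noise_poisson_scale < 0:
            raise ValueError("noise terms must be >= 0")
        for level in (self.stamp_level, self.overlay_level, self.label_offset,
                      self.tracer_level):
            if level < 0:
                raise ValueError("intensity levels must be >= 0")
        for combo in COMBOS:
            if self.cluster_density_per_100um2.get(combo, 0.0) < 0:
                raise ValueError("cluster densities must be >= 0")
            mean, sd = self.cluster_amplitude.get(combo, (0.0, 0.0))
            if mean < 0 or sd < 0:
                raise ValueError("cluster amplitudes must be >= 0")
        for pop in POPULATIONS:
            if self.cell_background_level.get(pop, 0.0) < 0:
                raise ValueError("cell background levels must be >= 0")
        mean_r, sd_r = self.cell_radius_um
        if mean_r <= 0 or sd_r < 0:
            raise ValueError("cell_radius_um mean must be > 0, sd >= 0")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame_size_px"] = list(self.frame_size_px)
        d["cell_radius_um"] = list(self.cell_radius_um)
        d["cluster_density_per_100um2"] = {
            f"{p}/{s}": v for (p, s), v in self.cluster_density_per_100um2.items()
        }
        d["cluster_amplitude"] = {
            f"{p}/{s}": list(v) for (p, s), v in self.cluster_amplitude.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneParams":
        d = dict(d)
        d["frame_size_px"] = tuple(d["frame_size_px"])
        d["cell_radius_um"] = tuple(d["cell_radius_um"])
        d["cluster_density_per_100um2"] = {
            tuple(k.split("/")): v for k, v in d["cluster_density_per_100um2"].items()
        }
        d["cluster_amplitude"] = {
            tuple(k.split("/")): tuple(v) for k, v in d["cluster_amplitude"].items()
        }
        return cls(**d)


@dataclass
class ClusterParams:
    """Microcluster detection settings.

    noise_tolerance is the required topographic prominence of a local
    maximum (a.u.).  When None it is resolved per image as
    ``mad_k × 1.4826 × MAD`` of the in-cell pixel values, a robust noise
    scale that transfers across intensity scales.
    """

    noise_tolerance: Optional[float] = None
    mad_k: float = 5.0
    max_footprint_radius_um: float = 0.5
    min_peak_value: Optional[float] = None
    segmented: bool = True  # False: footprints are the maxima pixels only

    def __post_init__(self):
        if self.noise_tolerance is not None and self.noise_tolerance <= 0:
            raise ValueError("noise_tolerance must be > 0")
        if self.mad_k <= 0:
            raise ValueError("mad_k must be > 0")
        if self.max_footprint_radius_um <= 0:
            raise ValueError("max_footprint_radius_um must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterParams":
        return cls(**d)


@dataclass
class ThresholdConfig:
    """Per-channel threshold settings for mask generation."""

    stripe_method: str = "otsu"
    stripe_value: Optional[float] = None
    cell_method: str = "otsu"
    cell_value: Optional[float] = None
    tracer_method: str = "fixed"  # tracer is often saturated; Otsu is unstable
    tracer_value: float = 50.0
    min_object_px: int = 16
    fill_holes: bool = True
    min_cell_area_um2: float = 30.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        return cls(**d)


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    mode: str = "synthetic"  # or "tiff_dir"
    input_dir: Optional[str] = None
    scene: SceneParams = field(default_factory=SceneParams)
    n_images: int = 12
    vary_configurations: bool = True  # cycle stamp/overlay and label swaps
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    alpha: float = 0.05
    include_interaction: bool = False
    block_by_image: bool = True
    equal_var: bool = True
    bonferroni_family: Optional[int] = None
    output_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("synthetic", "tiff_dir"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "tiff_dir" and not self.input_dir:
            raise ValueError("tiff_dir mode requires input_dir")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene"] = self.scene.to_dict()
        d["thresholds"] = self.thresholds.to_dict()
        d["cluster"] = self.cluster.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["scene"] = SceneParams.from_dict(d["scene"])
        d["thresholds"] = ThresholdConfig.from_dict(d["thresholds"])
        d["cluster"] = ClusterParams.from_dict(d["cluster"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
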