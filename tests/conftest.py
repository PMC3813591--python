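import numpy as np
import pytest

from stripecluster import pipeline
from stripecluster.params import RunConfig, SceneParams
from stripecluster.synthgen import render_image_set


def small_scene(seed=0, **overrides):
    """A quick-to-render scene used by most unit tests."""
    defaults = dict(frame_size_px=(256, 256), n_cells=4,
                    cell_radius_um=(4.5, 0.5), stripe_period_px=24, seed=seed)
    defaults.update(overrides)
    return SceneParams(**defaults)


@pytest.fixture(scope="session")
def default_render():
    """One default-sized field rendered once for the whole session."""
    scene = SceneParams(seed=11)
    image_set, truth = render_image_set(scene)
    return scene, image_set, truth


@pytest.fixture(scope="session")
def processed_fields():
    """Six default-SNR fields run through the full per-image pipeline,
    shared by the recovery tests (segmentation, clusters, quantify)."""
    out = []
    for seed in range(6):
        scene = SceneParams(seed=100 + seed)
        image_set, truth = render_image_set(scene)
        config = RunConfig(scene=scene, n_images=1,
                           vary_configurations=False)
        result = pipeline.process_image(image_set, config)
        out.append((scene, image_set, truth, result))
    return out
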