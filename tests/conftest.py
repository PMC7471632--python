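import dataclasses

import numpy as np
import pytest

from cytomorph import synth
from cytomorph.segment import SegmentationParams, segment_cells
from cytomorph.morphometry import build_morphometry_table


def small_config(seed: int = 7, **overrides) -> synth.SynthConfig:
    """Desk-scale study conditions: thin bands, small strip, fast to render."""
    def shrink(specs):
        thick = (50.0, 45.0, 80.0, 40.0, 70.0, 70.0)
        return [dataclasses.replace(s, thickness=t) for s, t in zip(specs, thick)]

    base = dict(
        layers_left=shrink(synth.default_layer_specs("left")),
        layers_right=shrink(synth.default_layer_specs("right")),
        strip_width=200.0,
        n_glial_specks=8,
        n_large_artifacts=1,
        n_vessels=1,
        seed=seed,
    )
    base.update(overrides)
    return synth.SynthConfig(**base)


@pytest.fixture(scope="session")
def small_section():
    """One rendered left section of the small study, with ground truth."""
    return synth.generate_section(small_config(), "left")


@pytest.fixture(scope="session")
def small_segmentation(small_section):
    image, layer_map, truth = small_section
    comps = segment_cells(image, layer_map, SegmentationParams())
    return image, layer_map, truth, comps


@pytest.fixture(scope="session")
def small_table(small_segmentation):
    _, _, truth, comps = small_segmentation
    return truth, build_morphometry_table(comps)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
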