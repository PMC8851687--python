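import numpy as np
import pytest

from adiposcreen import synthetic_plate as sp


@pytest.fixture
def effect_model():
    return sp.EffectModel(
        ec50=1.0,
        hill=1.5,
        base_frac=0.05,
        max_frac=0.6,
        intensity_per_area=2000.0,
    )


@pytest.fixture
def placement():
    # droplet gap >= 4 * blur_sigma so segmentation can be exact
    return sp.PlacementConfig(droplet_min_gap=6.0)


@pytest.fixture
def imaging_config():
    return sp.ImagingConfig(field_shape=(256, 256), fields_per_well=1)


@pytest.fixture
def field_factory(effect_model, placement):
    """Callable: (seed, n_cells, frac, config) -> (FieldTruth, FieldImages)."""

    def make(seed=0, n_cells=10, frac=0.6, config=None, render_seed=0):
        config = config or sp.ImagingConfig(field_shape=(256, 256), fields_per_well=1)
        truth = sp.simulate_field_truth(
            np.random.default_rng(seed), "A1", 0, frac, n_cells,
            effect_model, config, placement,
        )
        return truth, sp.render_field(truth, config, seed=render_seed)

    return make
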