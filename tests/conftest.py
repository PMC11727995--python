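import logging

import numpy as np
import pytest

from woundscreen import WoundSceneParams

# undersized-image warnings are expected noise for the 256 px test scenes
logging.getLogger("woundscreen.pipeline").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_scene():
    """256×256 scene defaults: same geometry as the full-size default,
    scaled down so property tests stay fast."""

    def make(**overrides):
        base = dict(
            image_size=(256, 256),
            incision_length_px=140.0,
            staple_spacing_px=20.0,
            staple_length_px=14.0,
            erythema_halfwidth_px=18.0,
        )
        base.update(overrides)
        return WoundSceneParams(**base)

    return make
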