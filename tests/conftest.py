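import numpy as np
import pytest

import weedmap as wm


@pytest.fixture(scope="session")
def small_scene():
    """A 256×256 field scene with 30% weed coverage, deterministic."""
    spec = wm.FieldSpec(256, 256, target_weed_coverage=0.30, seed=42)
    return wm.generate_scene(spec)


@pytest.fixture(scope="session")
def tiny_model():
    """A narrow FCN-4s for fast forward passes (1/16-width backbone)."""
    return wm.build_model(wm.FCNConfig("fcn4s", backbone_scale=1 / 16, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_label_map(rng, h, w, ignore_frac=0.0, gsd=0.005):
    codes = rng.integers(0, 3, (h, w)).astype(np.uint8)
    if ignore_frac:
        codes[rng.random((h, w)) < ignore_frac] = wm.CODE_IGNORE
    return wm.LabelMap(codes, wm.GeoRef(gsd, (0.0, h * gsd)))
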