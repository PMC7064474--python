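import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from nucseg import stains, synth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 224x224 scene with overlapping nuclei."""
    spec = synth.SceneSpec(height=224, width=224, n_nuclei=8,
                           radius_range=(11.0, 18.0), overlap_fraction=0.5,
                           seed=900)
    return synth.generate_scene(spec)


@pytest.fixture(scope="session")
def small_scene_hematoxylin(small_scene):
    return stains.hematoxylin_image(small_scene.rgb)
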