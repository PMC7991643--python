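import numpy as np
import pytest

from virtustain import simgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A 96x96 field with a few cells, shared across read-only tests."""
    return simgen.generate_scene(
        4, field_size=(96, 96), seed=7, size_scale=0.45, localization="membrane"
    )


@pytest.fixture(scope="session")
def training_pairs():
    """Small paired training set with a deterministic phase->fluorescence
    mapping (fixed unit expression, membrane localization, no noise)."""
    pairs = []
    for i in range(48):
        scene = simgen.generate_scene(
            3, field_size=(64, 64), seed=1000 + i, size_scale=0.35,
            localization="membrane",
        )
        pairs.append(simgen.render_pair(scene, "CD105"))
    return pairs


@pytest.fixture(scope="session")
def heldout_pairs():
    pairs = []
    for i in range(12):
        scene = simgen.generate_scene(
            3, field_size=(64, 64), seed=9000 + i, size_scale=0.35,
            localization="membrane",
        )
        pairs.append(simgen.render_pair(scene, "CD105"))
    return pairs
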