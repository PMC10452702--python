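"""Shared fixtures: small synthetic scenes and patch sets.

Everything is generated programmatically and seeded, so the suite needs no
stored data.
"""

from __future__ import annotations

import numpy as np
import pytest

from dropcell import synthgen


@pytest.fixture(scope="session")
def small_scene():
    """A small frame with a handful of droplets and its ground truth."""
    cfg = synthgen.SceneConfig(
        frame_width=256, frame_height=192, n_droplets=20, cpd_lambda=0.8, seed=5
    )
    img, truth = synthgen.render_scene(cfg)
    return cfg, img, truth


@pytest.fixture(scope="session")
def tiny_patches():
    """A small balanced patch dataset (40 per category)."""
    cfg = synthgen.SceneConfig(cpd_lambda=0.8, seed=17)
    return synthgen.make_patch_dataset(cfg, 40)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
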