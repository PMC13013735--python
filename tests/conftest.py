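"""Shared fixtures: textured frames and small synthetic scenes."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from clawtrack import SceneConfig, generate_scene, run_tracking


def textured_frame(shape=(128, 128), seed=0, smooth=1.5):
    """A random smooth texture with enough gradient for flow to grip."""
    rng = np.random.default_rng(seed)
    return gaussian_filter(rng.normal(128.0, 30.0, shape), smooth)


def shifted_pair(dx, dy, shape=(128, 128), seed=0):
    """Frame pair related by a circular rigid shift of (dx, dy) pixels."""
    a = textured_frame(shape, seed)
    b = np.roll(a, shift=(dy, dx), axis=(0, 1))
    return a, b


@pytest.fixture
def frame_pair_maker():
    return shifted_pair


@pytest.fixture(scope="session")
def small_scene():
    """3 clean, well-separated wavers; 10 s at 30 fps. Shared across tests."""
    cfg = SceneConfig(
        n_wavers=3,
        n_frames=300,
        width=360,
        height=280,
        noise_sigma=0.0,
        min_separation=110,
        seed=11,
    )
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def small_scene_tracks(small_scene):
    seq, truth = small_scene
    return run_tracking(seq)
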