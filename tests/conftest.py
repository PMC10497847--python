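"""Shared fixtures: small rendered scenes reused across morphometry tests."""

from __future__ import annotations

import numpy as np
import pytest

from spinepipe.synth import ImageSceneConfig, render_scene
from spinepipe.synth.spines import SpineShapeSpec

STRAIGHT_PATH = np.array([[2.5, 17.9], [33.3, 17.9]])


def make_scene(specs, *, noise=True, psf=0.1, seed=1, shape=(512, 512), **kw):
    """Render a 512-px scene around the standard straight dendrite."""
    defaults = dict(
        dendrite_path=STRAIGHT_PATH,
        spine_specs=list(specs),
        image_shape=shape,
        psf_sigma=psf,
        photon_scale=500.0,
        background_level=10.0 if noise else 0.0,
        read_noise_sd=2.0 if noise else 0.0,
        poisson_noise=noise,
        seed=seed,
    )
    defaults.update(kw)
    return render_scene(ImageSceneConfig(**defaults))


@pytest.fixture(scope="session")
def mushroom_scene():
    """One clean mushroom spine (L=1.0, W=0.6) pointing away from the tube."""
    spec = SpineShapeSpec(
        "mushroom", length=1.0, head_width=0.6, neck_width=0.3,
        orientation=-np.pi / 2, attachment=15.0,
    )
    image, truth = make_scene([spec], noise=False)
    return spec, image, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230731)
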