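"""Shared fixtures: scaled-down species presets and cached synthetic retinas.

Full-size retinas are expensive to simulate; the fixtures use area-reduced
variants of the built-in presets (identical densities, soma sizes, gradients
and injury courses — only the footprint shrinks), which preserves every
per-unit-area property the tests probe.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

import rgcquant as rq

# area scale factors for the test-sized retinas
TEST_AREA_SCALE = {
    ("mouse", "10w"): 0.15,
    ("zebrafish", "21w"): 0.2,
    ("killifish", "6w"): 0.2,
    ("killifish", "18w"): 0.15,
}

PRESET_KEYS = list(TEST_AREA_SCALE)


def scaled_preset(species: str, age: str, scale: float | None = None) -> rq.SpeciesPreset:
    full = rq.make_preset(species, age)
    scale = TEST_AREA_SCALE[(species, age)] if scale is None else scale
    return rq.make_preset(species, age, retinal_area=full.retinal_area * scale)


@pytest.fixture(scope="session")
def mouse_preset():
    return scaled_preset("mouse", "10w")


@pytest.fixture(scope="session")
def fish_preset():
    return scaled_preset("killifish", "6w")


@pytest.fixture(scope="session")
def mouse_retina(mouse_preset):
    return rq.generate_retina(mouse_preset, dpi=0, pixel_size=1.0, seed=11)


@pytest.fixture(scope="session")
def fish_retina(fish_preset):
    return rq.generate_retina(fish_preset, dpi=0, pixel_size=1.0, seed=7)


@pytest.fixture(scope="session")
def mouse_measurement(mouse_retina, mouse_preset):
    return rq.analyze_image(mouse_retina.image, preset=mouse_preset)


@pytest.fixture(scope="session")
def fish_measurement(fish_retina, fish_preset):
    return rq.analyze_image(fish_retina.image, preset=fish_preset)


def make_spot_image(
    positions_um,
    shape_px,
    pixel_size=1.0,
    fwhm_um=12.0,
    amplitude=600.0,
    background=300.0,
    noise_sigma=60.0,
    seed=0,
):
    """Small synthetic frame: Gaussian spots over noisy background."""
    rng = np.random.default_rng(seed)
    img = np.zeros(shape_px, dtype=np.float64)
    sigma_px = fwhm_um / (2 * math.sqrt(2 * math.log(2))) / pixel_size
    k = int(math.ceil(4 * sigma_px))
    ax = np.arange(-k, k + 1)
    h, w = shape_px
    pos = np.asarray(positions_um, float).reshape(-1, 2) / pixel_size
    col = np.round(pos[:, 0]).astype(int)
    row = np.round(pos[:, 1]).astype(int)
    dx2 = (ax[None, :] - (pos[:, 0] - col)[:, None]) ** 2
    dy2 = (ax[None, :] - (pos[:, 1] - row)[:, None]) ** 2
    vals = amplitude * np.exp(-(dy2[:, :, None] + dx2[:, None, :]) / (2 * sigma_px**2))
    rr = row[:, None] + ax[None, :]
    cc = col[:, None] + ax[None, :]
    ok = (rr[:, :, None] >= 0) & (rr[:, :, None] < h) & (cc[:, None, :] >= 0) & (cc[:, None, :] < w)
    ridx = rr[:, :, None].clip(0, h - 1)
    cidx = cc[:, None, :].clip(0, w - 1)
    np.add.at(img.ravel(), (ridx * w + cidx).ravel(), (vals * ok).ravel())
    img += background
    if noise_sigma > 0:
        img += rng.normal(0, noise_sigma, shape_px)
    return rq.CalibratedImage(np.clip(img, 0, 65535).astype(np.uint16), pixel_size)


@pytest.fixture
def spot_image_factory():
    return make_spot_image
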