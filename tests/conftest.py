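"""Shared fixtures: small synthetic wells with known ground truth.

Everything is generated at test time; session scope keeps the rendered
textures (the slowest fixtures) to one build each.
"""

from __future__ import annotations

import numpy as np
import pytest

from swirlquant import (
    OrientationField,
    TextureSpec,
    comet_spec,
    compute_orientation_field,
    spiral_spec,
    synthesize_texture,
    triradius_spec,
)

SIZE = 256
WINDOW_SIGMA = 10  # analysis window scaled to the small test wells


def stripe_image(alpha_deg: float, size: int = 128, omega: float = 0.5) -> np.ndarray:
    """Noiseless sinusoidal stripes at display angle *alpha_deg* (y up)."""
    a = np.radians(alpha_deg)
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    y_up = -rows
    return np.sin(omega * (cols * np.sin(a) - y_up * np.cos(a)))


def make_field(theta_deg: np.ndarray, coherency: np.ndarray | None = None) -> OrientationField:
    """OrientationField from a raw angle array (unit coherency by default)."""
    theta_deg = np.asarray(theta_deg, dtype=float)
    if coherency is None:
        coherency = np.ones_like(theta_deg)
    return OrientationField(theta_deg=theta_deg, coherency=coherency,
                            energy=np.ones_like(theta_deg))


@pytest.fixture(scope="session")
def comet_well():
    spec = comet_spec(SIZE, seed=11)
    image, angles = synthesize_texture(spec)
    return spec, image, angles


@pytest.fixture(scope="session")
def spiral_well():
    spec = spiral_spec(SIZE, seed=12)
    image, angles = synthesize_texture(spec)
    return spec, image, angles


@pytest.fixture(scope="session")
def triradius_well():
    spec = triradius_spec(SIZE, seed=13)
    image, angles = synthesize_texture(spec)
    return spec, image, angles


@pytest.fixture(scope="session")
def uniform_well():
    spec = TextureSpec(width_px=SIZE, height_px=SIZE, background_theta_deg=30.0, seed=14)
    image, angles = synthesize_texture(spec)
    return spec, image, angles


@pytest.fixture(scope="session")
def comet_field(comet_well):
    _, image, _ = comet_well
    return compute_orientation_field(image, window_sigma=WINDOW_SIGMA)
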