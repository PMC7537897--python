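import numpy as np
import pytest

import semmorph as sm


@pytest.fixture
def disc_image():
    """Noise-free two-valued disc (0.8 on 0.2), with its true mask."""
    px = np.full((100, 100), 0.2)
    yy, xx = np.ogrid[:100, :100]
    mask = (yy - 50) ** 2 + (xx - 50) ** 2 <= 30**2
    px[mask] = 0.8
    return sm.CalibratedImage(px, 50.0), mask


@pytest.fixture
def ring_scene():
    """Seeded 6-lamella ring, 11 nm period, amplitude ratio 0.6, sigma 0.03."""
    ring = sm.LamellarRing(center=(200, 200), inner_radius_nm=80.0, n_layers=6,
                           period_nm=11.0, amplitude_ratio=0.6, contrast=0.5)
    image, truth = sm.generate_scene(
        [ring], sm.NoiseModel(gaussian_sigma=0.03), (400, 400), 1.0, seed=7
    )
    return image, truth, ring
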