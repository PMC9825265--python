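import numpy as np
import pytest

from clonemorph.io import LabelImage
from clonemorph.synthetic import (
    SyntheticPopulationSpec,
    SyntheticSpheroidSpec,
    generate_population,
    generate_spheroid_stack,
)


def rasterize_disc(radius_um: float, pixel_size: float = 1.0, pad: int = 4) -> np.ndarray:
    """Boolean disc mask; center at the array center (pixel-center convention)."""
    r_px = radius_um / pixel_size
    n = int(2 * r_px) + 2 * pad + 1
    c = (n - 1) / 2
    rr, cc = np.mgrid[0:n, 0:n]
    return (rr - c) ** 2 + (cc - c) ** 2 <= r_px ** 2


def label_image_from_masks(masks, pixel_size: float = 1.0, shape=None) -> LabelImage:
    shape = shape or masks[0].shape
    pixels = np.zeros(shape, dtype=np.int32)
    for i, m in enumerate(masks, start=1):
        pixels[m] = i
    return LabelImage(pixels, pixel_size)


def sierpinski_carpet(depth: int) -> np.ndarray:
    m = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        z = np.zeros_like(m)
        m = np.block([[m, m, m], [m, z, m], [m, m, m]])
    return m


@pytest.fixture(scope="session")
def small_population():
    """~60-cell synthetic population with exact planted ground truth."""
    spec = SyntheticPopulationSpec(n_cells=60, image_shape=(384, 384), seed=11)
    return generate_population(spec)


@pytest.fixture(scope="session")
def dense_population():
    spec = SyntheticPopulationSpec(n_cells=150, target_confluency=0.30,
                                   image_shape=(384, 384), seed=23)
    return generate_population(spec)


@pytest.fixture(scope="session")
def star_spheroid():
    """4-arm spheroid with 3 disseminated blobs, planted metrics."""
    spec = SyntheticSpheroidSpec(
        n_protrusions=4, protrusion_lengths=(250.0, 250.0, 300.0, 300.0),
        n_disseminated=3, disseminated_distances=(250.0, 300.0, 350.0),
        disseminated_areas=(400.0, 600.0, 800.0), seed=3)
    return generate_spheroid_stack(spec)
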