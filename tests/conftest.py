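import numpy as np
import pytest

from brainquant.containers import SectionImage
from brainquant.synthetic import SectionConfig, generate_section


def small_config(**overrides) -> SectionConfig:
    """A 1000x1000 um section: the smallest size whose default region
    layout still holds a 300x200 um test annotation in every region."""
    defaults = dict(width_um=1000.0, height_um=1000.0, seed=42)
    defaults.update(overrides)
    return SectionConfig(**defaults)


def small_tissue_params(**overrides):
    """Tissue mask parameters scaled to sub-mm2 test sections (the default
    1 mm2 minimum tissue area is meant for whole coronal sections)."""
    from brainquant.masks import MaskParams

    defaults = dict(min_area_um2=100_000.0)
    defaults.update(overrides)
    return MaskParams(**defaults)


@pytest.fixture(scope="session")
def demo_section():
    """One generated small section shared by read-only tests."""
    cfg = small_config()
    img, cells, annots = generate_section(cfg)
    return cfg, img, cells, annots


def disc_image(
    centers_um,
    radius_um=4.0,
    value=1000.0,
    shape=(128, 128),
    pixel_size_um=1.0,
    channels=("DAPI", "DsRed", "GFP"),
    background=0.0,
) -> SectionImage:
    """Hard-edged discs on the DAPI channel: an analytically known fixture."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    xu = (xx + 0.5) * pixel_size_um
    yu = (yy + 0.5) * pixel_size_um
    canvas = np.full(shape, background, dtype=float)
    for cx, cy in centers_um:
        canvas[(xu - cx) ** 2 + (yu - cy) ** 2 <= radius_um**2] = value
    pixels = np.stack([canvas] + [np.full(shape, background)] * (len(channels) - 1))
    return SectionImage(
        np.clip(pixels, 0, 65535).astype(np.uint16), channels, pixel_size_um
    )
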