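"""Shared test fixtures: small synthetic datasets rendered once per session."""

import numpy as np
import pytest

from histomag.fixtures import FixtureConfig, render_batch, render_image


@pytest.fixture(scope="session")
def clean_cfg():
    """No jitter, unit gains: every stain statistic is exactly recoverable."""
    return FixtureConfig(image_size=64, magnifications=(40, 100, 200, 400),
                         images_per_class_per_mag=3, seed=3)


@pytest.fixture(scope="session")
def clean_renders(clean_cfg):
    """list of (image, record) over all classes/magnifications."""
    out = []
    for mag in clean_cfg.magnifications:
        for cls in ("benign", "malignant"):
            for i in range(clean_cfg.images_per_class_per_mag):
                out.append(render_image(clean_cfg, cls, mag, i))
    return out


@pytest.fixture(scope="session")
def corrupted_cfg():
    """Jitter + gains + contrast: every pipeline stage has a defect to fix."""
    return FixtureConfig(image_size=64, magnifications=(40, 100, 200, 400),
                         images_per_class_per_mag=3, seed=11,
                         stain_jitter_deg=5.0,
                         illumination_gain_range=(0.85, 1.15),
                         contrast_jitter_range=(-0.1, 0.1))


@pytest.fixture(scope="session")
def corrupted_renders(corrupted_cfg):
    out = []
    for mag in corrupted_cfg.magnifications:
        for cls in ("benign", "malignant"):
            for i in range(corrupted_cfg.images_per_class_per_mag):
                out.append(render_image(corrupted_cfg, cls, mag, i))
    return out


@pytest.fixture(scope="session")
def training_batch():
    """200 separable images at one magnification for learnability checks."""
    cfg = FixtureConfig(image_size=64, magnifications=(40,),
                        images_per_class_per_mag=100, seed=5)
    images, labels, _ = render_batch(cfg)
    return images, labels


def angular_degrees(u, v):
    cosine = np.clip(
        np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))
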