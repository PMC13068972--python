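"""Synthetic BreakHis-like image generator with known stain ground truth.

Images are formed in transmitted-light space by Beer-Lambert mixing of two
stains: elliptical "nuclei" carry the hematoxylin-like concentration and a
smooth stromal texture carries the eosin-like one.  Per-image channel gains
and contrast jitter corrupt the render so that every downstream
normalization stage has a defect to correct, and class-dependent nuclear
density provides a learnable classification signal.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigError, HistomagError

CLASSES = ("benign", "malignant")
MAGNIFICATIONS = (40, 100, 200, 400)

#: per-magnification object-radius multiplier (higher zoom -> larger objects)
DEFAULT_NUCLEI_SCALE = {40: 1.0, 100: 1.5, 200: 2.2, 400: 3.2}


def default_stain_basis() -> np.ndarray:
    """Fixed 3x2 stain basis with unit-norm nonnegative columns.

    Column 0 is the hematoxylin-like direction, column 1 the eosin-like one;
    the hematoxylin column has the larger red-channel optical-density
    component.  Values follow standard H&E literature conventions.
    """
    basis = np.array([[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]], dtype=float)
    return basis / np.linalg.norm(basis, axis=0, keepdims=True)


@dataclass
class FixtureConfig:
    """Parameters of a synthetic dataset build.  ``seed`` fixes everything."""

    images_per_class_per_mag: int = 5
    magnifications: tuple[int, ...] = MAGNIFICATIONS
    image_size: int = 224
    stain_basis_true: np.ndarray = field(default_factory=default_stain_basis)
    stain_jitter_deg: float = 0.0
    illumination_gain_range: tuple[float, float] = (1.0, 1.0)
    contrast_jitter_range: tuple[float, float] = (0.0, 0.0)
    nuclei_density: dict[str, float] = field(
        default_factory=lambda: {"benign": 14.0, "malignant": 28.0}
    )
    nuclei_radius_factor: dict[str, float] = field(
        default_factory=lambda: {"benign": 1.0, "malignant": 1.3}
    )
    nuclei_scale_per_mag: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_NUCLEI_SCALE)
    )
    background_intensity: float = 240.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.images_per_class_per_mag < 1:
            raise ConfigError("images_per_class_per_mag must be >= 1")
        if self.image_size < 32:
            raise ConfigError("image_size < 32 is too small to place objects")
        b = np.asarray(self.stain_basis_true, dtype=float)
        if b.shape != (3, 2):
            raise ConfigError("stain_basis_true must be 3x2")
        if np.any(b < 0):
            raise ConfigError("stain_basis_true entries must be nonnegative")
        if not np.allclose(np.linalg.norm(b, axis=0), 1.0, atol=1e-8):
            raise ConfigError("stain_basis_true columns must be unit-norm")
        lo, hi = self.illumination_gain_range
        if not (0.0 < lo <= hi <= 2.0):
            raise ConfigError("illumination_gain_range must lie in (0, 2]")
        bad = set(self.magnifications) - set(MAGNIFICATIONS)
        if bad:
            raise ConfigError(f"unknown magnifications: {sorted(bad)}")


@dataclass
class GroundTruthRecord:
    """Generation-time ground truth for one rendered image."""

    path: str
    class_label: str
    magnification: int
    stain_basis_used: np.ndarray
    illumination_gain_used: np.ndarray
    nuclei_count: int


def _image_rng(cfg: FixtureConfig, class_label: str, magnification: int, index: int):
    """Per-image RNG stream, reproducible independently of build order."""
    key = (CLASSES.index(class_label), magnification, index)
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


def _jitter_basis(basis: np.ndarray, jitter_deg: float, rng) -> np.ndarray:
    """Rotate each column by an angle <= jitter_deg toward a random direction."""
    if jitter_deg <= 0:
        return basis.copy()
    out = np.empty_like(basis)
    for j in range(2):
        v = basis[:, j]
        # random unit vector orthogonal to v
        u = rng.standard_normal(3)
        u -= u @ v * v
        u /= np.linalg.norm(u)
        theta = math.radians(rng.uniform(0.0, jitter_deg))
        w = math.cos(theta) * v + math.sin(theta) * u
        # floor keeps directions nonnegative and every stain estimable (the
        # densest fixture objects must clear the OD foreground threshold in
        # all channels); flooring only pulls a column toward its true value,
        # so the jitter bound is preserved
        w = np.clip(w, 0.045, None)
        out[:, j] = w / np.linalg.norm(w)
    return out


def _concentration_fields(
    cfg: FixtureConfig, class_label: str, magnification: int, rng
) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw the (H-like, E-like) concentration fields and the nucleus count."""
    s = cfg.image_size
    radius_scale = cfg.nuclei_scale_per_mag[magnification]
    # fewer, larger objects at higher zoom; density is the 40X mean count
    mean_count = cfg.nuclei_density[class_label] * (40.0 / magnification) ** 0.5
    count = max(1, int(round(mean_count * rng.uniform(0.85, 1.15))))

    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    hema = np.zeros((s, s))
    base_r = 0.03 * s * radius_scale * cfg.nuclei_radius_factor[class_label]
    for _ in range(count):
        cy, cx = rng.uniform(0, s, size=2)
        ry = base_r * rng.uniform(0.7, 1.3)
        rx = base_r * rng.uniform(0.7, 1.3)
        phi = rng.uniform(0, math.pi)
        dy, dx = yy - cy, xx - cx
        ya = math.cos(phi) * dy + math.sin(phi) * dx
        xa = -math.sin(phi) * dy + math.cos(phi) * dx
        inside = (ya / ry) ** 2 + (xa / rx) ** 2 <= 1.0
        hema[inside] = np.maximum(hema[inside], rng.uniform(0.9, 1.4))

    # smooth stromal texture for the eosin channel (low-pass random field);
    # dense patches reach concentrations whose red-channel OD clears the
    # Macenko foreground threshold, so eosin-dominant pixels are estimable
    from scipy.ndimage import gaussian_filter

    noise = rng.standard_normal((s, s))
    texture = gaussian_filter(noise, sigma=s / 24.0)
    tmin, tmax = texture.min(), texture.max()
    if tmax > tmin:
        texture = (texture - tmin) / (tmax - tmin)
    eosin = 0.15 + 2.1 * texture ** 2
    # eosin-dense stromal knots, drawn last so a few always stay uncovered
    for _ in range(6):
        cy, cx = rng.uniform(0, s, size=2)
        r = base_r * rng.uniform(0.8, 1.2)
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        hema[inside] = 0.0
        eosin[inside] = rng.uniform(3.4, 4.0)
    eosin[hema > 0] = 0.0  # nuclei displace stroma: pure-stain pixels exist
    return hema, eosin, count


def render_image(
    cfg: FixtureConfig, class_label: str, magnification: int, index: int
) -> tuple[np.ndarray, GroundTruthRecord]:
    """Render one synthetic H&E-like image.

    Pixels follow ``I = I0 * exp(-B @ C)`` with the jittered 3x2 basis ``B``
    and the 2xN concentration field ``C``; channel gains and contrast jitter
    are applied afterwards and the result is clipped to [0, 255].
    Deterministic for fixed ``(cfg.seed, class_label, magnification, index)``.
    """
    if class_label not in CLASSES:
        raise ConfigError(f"unknown class {class_label!r}")
    if magnification not in cfg.magnifications:
        raise ConfigError(f"magnification {magnification} not in config")
    rng = _image_rng(cfg, class_label, magnification, index)

    basis = _jitter_basis(np.asarray(cfg.stain_basis_true, float), cfg.stain_jitter_deg, rng)
    hema, eosin, count = _concentration_fields(cfg, class_label, magnification, rng)
    conc = np.stack([hema.ravel(), eosin.ravel()])  # 2 x N
    od = basis @ conc  # 3 x N
    img = cfg.background_intensity * np.exp(-od)  # transmitted light, 3 x N
    img = img.T.reshape(cfg.image_size, cfg.image_size, 3)

    gains = rng.uniform(*cfg.illumination_gain_range, size=3)
    img = img * gains
    c_lo, c_hi = cfg.contrast_jitter_range
    contrast = rng.uniform(c_lo, c_hi)
    img = img.mean() + (1.0 + contrast) * (img - img.mean())
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    record = GroundTruthRecord(
        path="",
        class_label=class_label,
        magnification=magnification,
        stain_basis_used=basis,
        illumination_gain_used=gains,
        nuclei_count=count,
    )
    return img, record


def render_batch(
    cfg: FixtureConfig, per_class: int | None = None
) -> tuple[np.ndarray, np.ndarray, list[GroundTruthRecord]]:
    """Render images in memory; returns (images, labels, records).

    ``labels`` is 0 for benign and 1 for malignant.  Convenience for tests
    and desk-scale training without touching the filesystem.
    """
    per_class = per_class or cfg.images_per_class_per_mag
    images, labels, records = [], [], []
    for mag in cfg.magnifications:
        for label, cls in enumerate(CLASSES):
            for i in range(per_class):
                img, rec = render_image(cfg, cls, mag, i)
                images.append(img)
                labels.append(label)
                records.append(rec)
    return np.stack(images), np.asarray(labels), records


def make_dataset(cfg: FixtureConfig, out_dir: str | os.PathLike, overwrite: bool = False):
    """Write the synthetic dataset in the BreakHis-style layout.

    Layout: ``out_dir/<class>/synthetic/sim/<mag>X/<name>.png`` with a
    ``manifest.csv`` (path,class,subtype,patient,magnification) and a
    ``ground_truth.csv`` holding the GroundTruthRecord fields.  Refuses a
    non-empty ``out_dir`` unless ``overwrite`` is set.

    Returns the manifest as a :class:`histomag.balance.DatasetManifest`.
    """
    from .balance import DatasetManifest

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not overwrite:
        raise HistomagError(f"output directory {out} is not empty (pass overwrite=True)")

    manifest_rows, gt_rows = [], []
    for cls in CLASSES:
        for mag in cfg.magnifications:
            d = out / cls / "synthetic" / "sim" / f"{mag}X"
            d.mkdir(parents=True, exist_ok=True)
            for i in range(cfg.images_per_class_per_mag):
                img, rec = render_image(cfg, cls, mag, i)
                path = d / f"{cls}_{mag}X_{i:04d}.png"
                Image.fromarray(img).save(path)
                rec.path = str(path)
                manifest_rows.append(
                    {
                        "path": str(path),
                        "class": cls,
                        "subtype": "synthetic",
                        "patient": "sim",
                        "magnification": mag,
                    }
                )
                gt_rows.append(rec)

    with open(out / "manifest.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["path", "class", "subtype", "patient", "magnification"])
        w.writeheader()
        w.writerows(manifest_rows)
    with open(out / "ground_truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["path", "class_label", "magnification", "stain_basis_used",
             "illumination_gain_used", "nuclei_count"]
        )
        for rec in gt_rows:
            w.writerow(
                [rec.path, rec.class_label, rec.magnification,
                 ";".join(f"{v:.8f}" for v in rec.stain_basis_used.ravel()),
                 ";".join(f"{v:.8f}" for v in rec.illumination_gain_used),
                 rec.nuclei_count]
            )

    return DatasetManifest.from_rows(
        [
            dict(
                path=r["path"], class_label=r["class"], subtype=r["subtype"],
                patient_id=r["patient"], magnification=r["magnification"],
                origin="original", split="unassigned", parent="",
            )
            for r in manifest_rows
        ]
    )
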