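"""Manifest scanning, class balancing, seeded augmentation and splitting.

The manifest is a table of (path, class_label, subtype, patient_id,
magnification, origin, split) rows driving every dataset operation:
per-magnification class counting, minority-class balancing plans, their
execution via seeded augmentation, and stratified 70/15/15 splitting.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigError, HistomagError

CLASSES = ("benign", "malignant")
MAGNIFICATIONS = (40, 100, 200, 400)
IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}

MANIFEST_COLUMNS = [
    "path", "class_label", "subtype", "patient_id",
    "magnification", "origin", "split", "parent",
]


@dataclass
class DatasetManifest:
    """Thin wrapper over a pandas DataFrame with the manifest schema."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ConfigError(f"manifest missing columns: {sorted(missing)}")
        if self.frame["path"].duplicated().any():
            raise ConfigError("manifest paths must be unique")

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "DatasetManifest":
        frame = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
        frame["magnification"] = frame["magnification"].astype(int)
        return cls(frame)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | os.PathLike) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "DatasetManifest":
        frame = pd.read_csv(path, keep_default_na=False)
        frame["magnification"] = frame["magnification"].astype(int)
        return cls(frame)


def scan_manifest(root_dir: str | os.PathLike) -> tuple[DatasetManifest, list[str]]:
    """Walk a BreakHis-style tree: <class>/<subtype>/<patient>/<mag>X/<file>.

    Returns the manifest plus a rejects report listing files whose layout
    could not be parsed (they are never silently dropped).
    """
    root = Path(root_dir)
    if not root.exists():
        raise HistomagError(f"root directory {root} does not exist")
    rows, rejects = [], []
    for path in sorted(root.rglob("*")):
        if not path.is_file() or path.suffix.lower() not in IMAGE_EXTENSIONS:
            if path.is_file() and path.name not in ("manifest.csv", "ground_truth.csv"):
                rejects.append(str(path))
            continue
        rel = path.relative_to(root).parts
        if len(rel) != 5 or rel[0] not in CLASSES or not rel[3].endswith("X"):
            rejects.append(str(path))
            continue
        try:
            mag = int(rel[3][:-1])
        except ValueError:
            rejects.append(str(path))
            continue
        if mag not in MAGNIFICATIONS:
            rejects.append(str(path))
            continue
        rows.append(dict(
            path=str(path), class_label=rel[0], subtype=rel[1], patient_id=rel[2],
            magnification=mag, origin="original", split="unassigned", parent="",
        ))
    if not rows:
        raise HistomagError(f"no image files found under {root}")
    return DatasetManifest.from_rows(rows), rejects


@dataclass
class ClassCountTable:
    """Cross-tabulation count[class, magnification] with totals."""

    counts: pd.DataFrame  # index = class, columns = magnifications

    def cell(self, class_label: str, magnification: int) -> int:
        return int(self.counts.loc[class_label, magnification])

    def class_total(self, class_label: str) -> int:
        return int(self.counts.loc[class_label].sum())

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())


def count_by_class_mag(manifest: DatasetManifest) -> ClassCountTable:
    """Exact (class x magnification) cross-tabulation of the manifest."""
    if len(manifest) == 0:
        raise HistomagError("empty manifest")
    tab = pd.crosstab(manifest.frame["class_label"], manifest.frame["magnification"])
    tab = tab.reindex(index=list(CLASSES), columns=sorted(tab.columns), fill_value=0)
    return ClassCountTable(counts=tab)


@dataclass
class BalancePlan:
    """Per-magnification minority class and generation deficit."""

    minority_class: dict[int, str]
    n_to_generate: dict[int, int]
    target_per_class: dict[int, int]


def plan_balance(counts: ClassCountTable) -> BalancePlan:
    """Equalize classes per magnification by topping up the minority class."""
    minority, deficit, target = {}, {}, {}
    for mag in counts.counts.columns:
        b = counts.cell("benign", mag)
        m = counts.cell("malignant", mag)
        if b == 0 or m == 0:
            raise HistomagError(f"magnification {mag}X has a class with zero images")
        minority[int(mag)] = "benign" if b <= m else "malignant"
        deficit[int(mag)] = abs(m - b)
        target[int(mag)] = max(b, m)
    return BalancePlan(minority_class=minority, n_to_generate=deficit, target_per_class=target)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentationSpec:
    """Enabled ops with parameter ranges; rotations restricted to 90-degree
    multiples for the rot90 op.  One geometric op is always applied so an
    augmented image never duplicates its parent."""

    p_horizontal_flip: float = 0.5
    p_vertical_flip: float = 0.5
    p_rot90: float = 0.5
    p_shift_scale_rotate: float = 0.5
    shift_frac: float = 0.0625
    scale_frac: float = 0.10
    max_degrees: float = 15.0
    p_brightness_contrast: float = 0.5
    brightness_delta: float = 0.2
    contrast_delta: float = 0.2
    p_hsv: float = 0.5
    hue_shift: float = 10.0
    sat_shift: float = 20.0
    val_shift: float = 10.0
    p_gaussian_blur: float = 0.5
    blur_kernels: tuple[int, ...] = (3, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_horizontal_flip", "p_vertical_flip", "p_rot90",
                     "p_shift_scale_rotate", "p_brightness_contrast",
                     "p_hsv", "p_gaussian_blur"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")


def _stream_rng(seed: int, stream_key) -> np.random.Generator:
    import zlib

    digest = zlib.crc32(repr(stream_key).encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(digest,)))


def _shift_scale_rotate(img: np.ndarray, shift, scale, degrees, rng) -> np.ndarray:
    from scipy.ndimage import affine_transform

    h, w = img.shape[:2]
    angle = math.radians(rng.uniform(-degrees, degrees))
    s = 1.0 + rng.uniform(-scale, scale)
    ty = rng.uniform(-shift, shift) * h
    tx = rng.uniform(-shift, shift) * w
    cos, sin = math.cos(angle), math.sin(angle)
    # output->input mapping around the image centre
    mat = np.array([[cos, -sin], [sin, cos]]) / s
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = centre - mat @ (centre + np.array([ty, tx]))
    out = np.empty_like(img)
    for c in range(3):
        out[..., c] = affine_transform(
            img[..., c], mat, offset=offset, order=1, mode="reflect", output=np.uint8
        )
    return out


def _brightness_contrast(img: np.ndarray, b_delta, c_delta, rng) -> np.ndarray:
    b = rng.uniform(-b_delta, b_delta) * 255.0
    c = 1.0 + rng.uniform(-c_delta, c_delta)
    out = (img.astype(float) - 127.5) * c + 127.5 + b
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _hsv_shift(img: np.ndarray, hue, sat, val, rng) -> np.ndarray:
    from skimage.color import hsv2rgb, rgb2hsv

    hsv = rgb2hsv(img.astype(float) / 255.0)
    hsv[..., 0] = (hsv[..., 0] + rng.uniform(-hue, hue) / 360.0) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] + rng.uniform(-sat, sat) / 255.0, 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] + rng.uniform(-val, val) / 255.0, 0, 1)
    return np.clip(np.rint(hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)


def _gaussian_blur(img: np.ndarray, kernels, rng) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    k = int(rng.choice(np.asarray(kernels)))
    sigma = 0.3 * ((k - 1) * 0.5 - 1) + 0.8  # standard kernel->sigma rule
    out = gaussian_filter(img.astype(float), sigma=(sigma, sigma, 0))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment_image(img: np.ndarray, spec: AugmentationSpec, stream_key) -> np.ndarray:
    """Apply the enabled ops with their probabilities, deterministically per
    ``(spec.seed, stream_key)``.  Output has the input's dimensions."""
    rng = _stream_rng(spec.seed, stream_key)
    out = np.asarray(img)
    geometric_applied = False
    if rng.random() < spec.p_horizontal_flip:
        out = out[:, ::-1]
        geometric_applied = True
    if rng.random() < spec.p_vertical_flip:
        out = out[::-1]
        geometric_applied = True
    if rng.random() < spec.p_rot90:
        k = int(rng.integers(1, 4))
        out = np.rot90(out, k)
        geometric_applied = True
    if rng.random() < spec.p_shift_scale_rotate:
        out = _shift_scale_rotate(np.ascontiguousarray(out), spec.shift_frac,
                                  spec.scale_frac, spec.max_degrees, rng)
        geometric_applied = True
    if rng.random() < spec.p_brightness_contrast:
        out = _brightness_contrast(out, spec.brightness_delta, spec.contrast_delta, rng)
    if rng.random() < spec.p_hsv:
        out = _hsv_shift(out, spec.hue_shift, spec.sat_shift, spec.val_shift, rng)
    if rng.random() < spec.p_gaussian_blur:
        out = _gaussian_blur(out, spec.blur_kernels, rng)
    if not geometric_applied:  # guarantee the output differs from its parent
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def execute_plan(
    manifest: DatasetManifest,
    plan: BalancePlan,
    spec: AugmentationSpec,
    out_dir: str | os.PathLike,
) -> DatasetManifest:
    """Generate the planned augmented minority images and merge the manifest.

    Parents are sampled uniformly with replacement from the minority-class
    originals of each magnification; originals are never modified.
    """
    out = Path(out_dir)
    frame = manifest.frame
    new_rows = []
    for mag, n_needed in plan.n_to_generate.items():
        if n_needed == 0:
            continue
        minority = plan.minority_class[mag]
        pool = frame[
            (frame["magnification"] == mag)
            & (frame["class_label"] == minority)
            & (frame["origin"] == "original")
        ]
        if pool.empty:
            raise HistomagError(f"no {minority} originals at {mag}X to augment")
        rng = _stream_rng(spec.seed, ("parent-sampling", mag))
        parent_idx = rng.integers(0, len(pool), size=n_needed)
        for i, pi in enumerate(parent_idx):
            parent = pool.iloc[int(pi)]
            img = np.asarray(Image.open(parent["path"]).convert("RGB"))
            aug = augment_image(img, spec, (mag, i, parent["path"]))
            dest_dir = out / minority / str(parent["subtype"]) / str(parent["patient_id"]) / f"{mag}X"
            dest_dir.mkdir(parents=True, exist_ok=True)
            stem = Path(parent["path"]).stem
            dest = dest_dir / f"{stem}_aug{i:05d}.png"
            Image.fromarray(aug).save(dest)
            new_rows.append(dict(
                path=str(dest), class_label=minority, subtype=parent["subtype"],
                patient_id=parent["patient_id"], magnification=mag,
                origin="augmented", split="unassigned", parent=parent["path"],
            ))
    merged = pd.concat([frame, pd.DataFrame(new_rows, columns=MANIFEST_COLUMNS)],
                       ignore_index=True)
    merged["magnification"] = merged["magnification"].astype(int)
    return DatasetManifest(merged)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 42
    unit: str = "image"

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios) or abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ConfigError("ratios must be positive and sum to 1")
        if self.unit not in ("image", "patient"):
            raise ConfigError("unit must be 'image' or 'patient'")


def largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Partition n into parts proportional to ratios, largest-remainder rule."""
    exact = [n * r for r in ratios]
    parts = [int(math.floor(e)) for e in exact]
    remainder = n - sum(parts)
    order = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - parts[i]), i))
    for i in order[:remainder]:
        parts[i] += 1
    return parts


def stratified_split(manifest: DatasetManifest, spec: SplitSpec) -> DatasetManifest:
    """Assign train/val/test within each (magnification, class) stratum.

    Image-unit mode shuffles rows per stratum (seeded) and cuts at
    largest-remainder sizes; patient-unit mode assigns whole patients
    greedily to the split furthest below its image-count target.
    """
    frame = manifest.frame.copy()
    frame["split"] = "unassigned"
    names = ("train", "val", "test")
    for (mag, cls), idx in frame.groupby(["magnification", "class_label"]).groups.items():
        idx = list(idx)
        rng = _stream_rng(spec.seed, ("split", int(mag), str(cls)))
        if spec.unit == "image":
            if len(idx) < 3:
                raise HistomagError(f"stratum ({mag}X, {cls}) too small to split: {len(idx)}")
            perm = rng.permutation(len(idx))
            sizes = largest_remainder(len(idx), spec.ratios)
            start = 0
            for name, size in zip(names, sizes):
                take = [idx[p] for p in perm[start:start + size]]
                frame.loc[take, "split"] = name
                start += size
        else:
            patients = sorted(frame.loc[idx, "patient_id"].unique())
            if len(patients) < 3:
                raise HistomagError(f"stratum ({mag}X, {cls}) has too few patients to split")
            rng.shuffle(patients)
            n = len(idx)
            targets = [n * r for r in spec.ratios]
            filled = [0.0, 0.0, 0.0]
            for patient in patients:
                rows = [i for i in idx if frame.loc[i, "patient_id"] == patient]
                j = int(np.argmax([t - f for t, f in zip(targets, filled)]))
                frame.loc[rows, "split"] = names[j]
                filled[j] += len(rows)
    return DatasetManifest(frame)
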