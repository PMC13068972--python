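"""Four-stage stain/color normalization pipeline.

Stage order: CLAHE on the LAB luminance channel, per-channel CDF histogram
matching against a reference, Shades-of-Gray color constancy (Minkowski
p-norm illuminant), and Macenko optical-density stain normalization.

All operations take and return H x W x 3 uint8 RGB arrays in [0, 255].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import lab2rgb, rgb2lab

from .errors import (
    BackgroundOnlyError,
    ConfigError,
    DegenerateImageError,
    RankDeficientError,
    StageError,
)

log = logging.getLogger(__name__)

STAGES = ("clahe", "histmatch", "shades_of_gray", "macenko")


@dataclass
class PreprocessConfig:
    clip_limit: float = 3.0
    tile_grid: tuple[int, int] = (8, 8)
    minkowski_p: float = 6.0
    I0: float = 240.0
    beta: float = 0.15
    epsilon: float = 1e-6
    concentration_percentile: float = 99.0
    #: "svd" takes the raw top-2 right singular vectors (the literal
    #: deconvolution formula); "percentile" uses the original Macenko
    #: angle-percentile extreme directions, which is the mode capable of
    #: recovering non-orthogonal stain vectors and is the pipeline default.
    basis_mode: str = "percentile"
    angle_percentile: float = 1.0
    # below: single-stain images under uint8 quantization sit near 2.5e-3,
    # genuine two-stain fixtures above ~9e-3
    rank_tolerance: float = 5e-3

    def __post_init__(self) -> None:
        if self.clip_limit <= 0:
            raise ConfigError("clip_limit must be > 0")
        if min(self.tile_grid) < 1:
            raise ConfigError("tile_grid dims must be >= 1")
        if self.minkowski_p < 1:
            raise ConfigError("minkowski_p must be >= 1")
        if not (0 < self.beta < self.I0):
            raise ConfigError("beta must satisfy 0 < beta < I0")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be > 0")
        if not (0 < self.concentration_percentile <= 100):
            raise ConfigError("concentration_percentile must be in (0, 100]")
        if self.basis_mode not in ("svd", "percentile"):
            raise ConfigError("basis_mode must be 'svd' or 'percentile'")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ConfigError("expected an H x W x 3 RGB image")
    if img.size == 0:
        raise DegenerateImageError("empty image")
    return img


# ---------------------------------------------------------------------------
# Stage 1: CLAHE in LAB
# ---------------------------------------------------------------------------

def _clahe_channel(chan: np.ndarray, clip_limit: float, tiles: tuple[int, int]) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of one uint8 channel.

    256-bin per-tile histograms clipped at ``clip_limit`` times the uniform
    bin height, excess redistributed uniformly, and bilinear inter-tile
    interpolation of the per-tile mappings.
    """
    h, w = chan.shape
    tr, tc = tiles
    if h < tr or w < tc:
        log.warning("image %dx%d smaller than tile grid %s; using a single global tile", h, w, tiles)
        tr = tc = 1
    tile_h = -(-h // tr)  # ceil
    tile_w = -(-w // tc)
    # pad by reflection so tiles divide evenly
    padded = np.pad(chan, ((0, tr * tile_h - h), (0, tc * tile_w - w)), mode="reflect")

    n_pix = tile_h * tile_w
    clip = max(1, int(clip_limit * n_pix / 256.0))
    maps = np.empty((tr, tc, 256))
    for i in range(tr):
        for j in range(tc):
            tile = padded[i * tile_h:(i + 1) * tile_h, j * tile_w:(j + 1) * tile_w]
            hist = np.bincount(tile.ravel(), minlength=256).astype(float)
            excess = np.sum(np.maximum(hist - clip, 0.0))
            hist = np.minimum(hist, clip) + excess / 256.0
            cdf = np.cumsum(hist)
            maps[i, j] = np.rint(cdf * (255.0 / n_pix))

    # bilinear interpolation between the four surrounding tile mappings
    ys = (np.arange(h) + 0.5) / tile_h - 0.5
    xs = (np.arange(w) + 0.5) / tile_w - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, tr - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, tc - 1)
    y1 = np.clip(y0 + 1, 0, tr - 1)
    x1 = np.clip(x0 + 1, 0, tc - 1)
    wy = np.clip(ys - y0, 0.0, 1.0)[:, None]
    wx = np.clip(xs - x0, 0.0, 1.0)[None, :]

    v = chan.astype(int)
    yy0 = y0[:, None]
    yy1 = y1[:, None]
    xx0 = x0[None, :]
    xx1 = x1[None, :]
    out = ((1 - wy) * (1 - wx) * maps[yy0, xx0, v]
           + (1 - wy) * wx * maps[yy0, xx1, v]
           + wy * (1 - wx) * maps[yy1, xx0, v]
           + wy * wx * maps[yy1, xx1, v])
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def apply_clahe(img: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Equalize only the LAB luminance channel; chroma passes through."""
    img = _check_image(img)
    lab = rgb2lab(img.astype(float) / 255.0)
    l8 = np.clip(np.rint(lab[..., 0] * 255.0 / 100.0), 0, 255).astype(np.uint8)
    l8 = _clahe_channel(l8, cfg.clip_limit, cfg.tile_grid)
    lab[..., 0] = l8.astype(float) * 100.0 / 255.0
    rgb = lab2rgb(lab)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Stage 2: histogram matching
# ---------------------------------------------------------------------------

def channel_cdfs(img: np.ndarray) -> np.ndarray:
    """Per-channel cumulative histograms over 256 levels; each ends at 1."""
    img = _check_image(img)
    n = img.shape[0] * img.shape[1]
    cdfs = np.empty((3, 256))
    for c in range(3):
        hist = np.bincount(img[..., c].ravel(), minlength=256)
        cdfs[c] = np.cumsum(hist) / n
    return cdfs


@dataclass
class ReferenceStats:
    """Serializable reference-image statistics used across the pipeline."""

    rgb_cdfs: np.ndarray  # 3 x 256, each row nondecreasing, ends at 1
    stain_basis_ref: np.ndarray | None = None  # 3 x 2
    robust_max_ref: np.ndarray | None = None  # 2-vector

    def __post_init__(self) -> None:
        cdfs = np.asarray(self.rgb_cdfs, float)
        if cdfs.shape != (3, 256):
            raise ConfigError("rgb_cdfs must be 3 x 256")
        if np.any(np.diff(cdfs, axis=1) < -1e-12) or not np.allclose(cdfs[:, -1], 1.0):
            raise ConfigError("each CDF must be nondecreasing and end at 1")
        self.rgb_cdfs = cdfs

    def to_json(self, path: str | Path) -> None:
        payload = {"rgb_cdfs": self.rgb_cdfs.tolist()}
        if self.stain_basis_ref is not None:
            payload["stain_basis_ref"] = np.asarray(self.stain_basis_ref).tolist()
        if self.robust_max_ref is not None:
            payload["robust_max_ref"] = np.asarray(self.robust_max_ref).tolist()
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceStats":
        payload = json.loads(Path(path).read_text())
        return cls(
            rgb_cdfs=np.asarray(payload["rgb_cdfs"]),
            stain_basis_ref=(np.asarray(payload["stain_basis_ref"])
                             if "stain_basis_ref" in payload else None),
            robust_max_ref=(np.asarray(payload["robust_max_ref"])
                            if "robust_max_ref" in payload else None),
        )


def build_reference_stats(img: np.ndarray, cfg: PreprocessConfig | None = None) -> ReferenceStats:
    """Compute CDFs plus, when possible, the Macenko basis and robust maxima."""
    cfg = cfg or PreprocessConfig()
    stats = ReferenceStats(rgb_cdfs=channel_cdfs(img))
    try:
        od = compute_od(img, cfg)
        basis = estimate_stain_basis(od, cfg)
        conc, robust_max = _concentrations(od, basis, cfg)
        stats.stain_basis_ref = basis
        stats.robust_max_ref = robust_max
    except (BackgroundOnlyError, RankDeficientError):
        pass
    return stats


def pick_reference(images: list[np.ndarray]) -> int:
    """Index of the image whose channel means are closest to the batch medians."""
    means = np.array([img.reshape(-1, 3).mean(axis=0) for img in images])
    med = np.median(means, axis=0)
    return int(np.argmin(np.linalg.norm(means - med, axis=1)))


def match_histogram(src: np.ndarray, ref_stats: ReferenceStats) -> np.ndarray:
    """Map each level i to the smallest reference level j with CDF_ref(j) >= CDF_src(i).

    Applied independently per RGB channel; the mapping is monotone
    nondecreasing, so the squared CDF distance to the reference never
    increases.
    """
    src = _check_image(src)
    src_cdfs = channel_cdfs(src)
    out = np.empty_like(src)
    for c in range(3):
        # searchsorted(left) returns the first j with cdf_ref[j] >= value
        mapping = np.searchsorted(ref_stats.rgb_cdfs[c], src_cdfs[c], side="left")
        mapping = np.clip(mapping, 0, 255).astype(np.uint8)
        out[..., c] = mapping[src[..., c]]
    return out


# ---------------------------------------------------------------------------
# Stage 3: Shades-of-Gray
# ---------------------------------------------------------------------------

def estimate_illuminant(img: np.ndarray, p: float) -> np.ndarray:
    """Per-channel Minkowski p-norm illuminant: ((1/(N*M)) sum I^p)^(1/p)."""
    if p < 1:
        raise ConfigError("p must be >= 1")
    img = _check_image(img).astype(float)
    # normalize to [0,1] before powering to avoid overflow at large p
    scaled = img / 255.0
    est = np.mean(scaled ** p, axis=(0, 1)) ** (1.0 / p)
    return est * 255.0


def shades_of_gray(img: np.ndarray, p: float = 6.0) -> np.ndarray:
    """Divide channels by their illuminant estimates, re-anchored to gray.

    The gray anchor is the median of the three estimates: a single corrupted
    channel is pulled onto the two clean ones (restoring the uncorrupted
    image exactly), a gray-world image is a fixed point, and the output's
    channel illuminants are equal (up to clipping/rounding).
    """
    img = _check_image(img)
    illum = estimate_illuminant(img, p)
    if np.any(illum == 0):
        raise DegenerateImageError("zero illuminant component (empty channel)")
    gains = np.median(illum) / illum
    out = img.astype(float) * gains
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Stage 4: Macenko stain normalization
# ---------------------------------------------------------------------------

@dataclass
class OpticalDensityMatrix:
    """N_pixels x 3 absorbances plus the source image shape."""

    values: np.ndarray
    source_shape: tuple[int, int]


def compute_od(img: np.ndarray, cfg: PreprocessConfig) -> OpticalDensityMatrix:
    """Element-wise OD = -log((I + eps) / I0), clamped at 0 for I >= I0."""
    img = _check_image(img).astype(float)
    od = -np.log((img + cfg.epsilon) / cfg.I0)
    od = np.maximum(od, 0.0)
    return OpticalDensityMatrix(values=od.reshape(-1, 3), source_shape=img.shape[:2])


def _foreground_mask(od: np.ndarray, beta: float) -> np.ndarray:
    """Tissue pixels: OD exceeds beta in every channel."""
    return np.all(od > beta, axis=1)


def _extreme_directions(fg: np.ndarray, plane: np.ndarray, alpha: float) -> np.ndarray:
    """Angle-percentile extreme directions of the projected OD cloud (3x2)."""
    coords = fg @ plane  # N x 2
    # orient the plane so projections are positive-dominant
    for k in range(2):
        if np.sum(coords[:, k]) < 0:
            coords[:, k] = -coords[:, k]
            plane[:, k] = -plane[:, k]
    phi = np.arctan2(coords[:, 1], coords[:, 0])
    lo, hi = np.percentile(phi, [alpha, 100.0 - alpha])
    v_lo = plane @ np.array([np.cos(lo), np.sin(lo)])
    v_hi = plane @ np.array([np.cos(hi), np.sin(hi)])
    return np.stack([v_lo, v_hi], axis=1)


def estimate_stain_basis(od: OpticalDensityMatrix, cfg: PreprocessConfig) -> np.ndarray:
    """SVD stain estimation on foreground OD pixels; returns the 3x2 basis.

    Column order: hematoxylin (larger red-channel OD component) first.
    ``cfg.basis_mode`` selects the raw singular vectors ("svd") or the
    original Macenko angle-percentile extremes ("percentile").
    """
    fg = od.values[_foreground_mask(od.values, cfg.beta)]
    if fg.shape[0] < 2:
        raise BackgroundOnlyError("background-only image: no foreground OD pixels above beta")
    _, s, vt = np.linalg.svd(fg, full_matrices=False)
    if s[1] < cfg.rank_tolerance * s[0]:
        raise RankDeficientError("single-stain / rank-deficient image")
    if cfg.basis_mode == "percentile":
        basis = _extreme_directions(fg, vt[:2].T.copy(), cfg.angle_percentile)
    else:
        basis = vt[:2].T.copy()
    # sign-correct to nonnegative-dominant, clamp residual negatives, normalize
    for k in range(2):
        if basis[:, k].sum() < 0:
            basis[:, k] = -basis[:, k]
    basis = np.clip(basis, 0.0, None)
    norms = np.linalg.norm(basis, axis=0)
    if np.any(norms == 0):
        raise RankDeficientError("degenerate stain direction after sign correction")
    basis /= norms
    if basis[0, 0] < basis[0, 1]:  # hematoxylin column carries more red OD
        basis = basis[:, ::-1]
    return basis


@dataclass
class ConcentrationMatrix:
    """2 x N_pixels stain concentrations and their per-stain robust maxima."""

    values: np.ndarray
    robust_max: np.ndarray


def stain_concentrations(
    img: np.ndarray, cfg: PreprocessConfig, basis: np.ndarray | None = None
) -> ConcentrationMatrix:
    """Per-pixel stain concentrations of an image (row 0 = hematoxylin)."""
    od = compute_od(img, cfg)
    if basis is None:
        basis = estimate_stain_basis(od, cfg)
    values, robust_max = _concentrations(od, basis, cfg)
    return ConcentrationMatrix(values=values, robust_max=robust_max)


def _concentrations(
    od: OpticalDensityMatrix, basis: np.ndarray, cfg: PreprocessConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares stain concentrations (2 x N) and per-stain robust maxima."""
    conc = np.linalg.pinv(basis) @ od.values.T
    conc = np.clip(conc, 0.0, None)
    fg = _foreground_mask(od.values, cfg.beta)
    pool = conc[:, fg] if fg.any() else conc
    robust_max = np.percentile(pool, cfg.concentration_percentile, axis=1)
    robust_max = np.maximum(robust_max, np.finfo(float).tiny)
    return conc, robust_max


def macenko_normalize(
    img: np.ndarray, cfg: PreprocessConfig, ref: ReferenceStats | None = None
) -> np.ndarray:
    """Stain-normalize one image.

    Literal mode (``ref=None``): concentrations divided by their own
    robust maxima and reconstructed with the source basis.  Reference-coupled
    mode: rows additionally scaled by ``ref.robust_max_ref`` and reconstructed
    with ``ref.stain_basis_ref``.
    """
    img = _check_image(img)
    if ref is not None and (ref.stain_basis_ref is None or ref.robust_max_ref is None):
        raise ConfigError("reference-coupled mode requires reference stain statistics")
    od = compute_od(img, cfg)
    basis = estimate_stain_basis(od, cfg)
    conc, robust_max = _concentrations(od, basis, cfg)
    conc_norm = conc / robust_max[:, None]
    if ref is not None:
        conc_norm = conc_norm * np.asarray(ref.robust_max_ref, float)[:, None]
        basis = np.asarray(ref.stain_basis_ref, float)
    out = cfg.I0 * np.exp(-(basis @ conc_norm))
    out = out.T.reshape(*od.source_shape, 3)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def preprocess(
    img: np.ndarray,
    cfg: PreprocessConfig,
    ref: ReferenceStats,
    stage_log: list | None = None,
) -> np.ndarray:
    """Apply CLAHE -> histogram match -> Shades-of-Gray -> Macenko, in order.

    Deterministic.  ``stage_log``, when given, receives one record per stage
    with the stage name and the post-stage channel means.  Any stage failure
    raises :class:`StageError` naming the stage.
    """
    stage_fns = {
        "clahe": lambda x: apply_clahe(x, cfg),
        "histmatch": lambda x: match_histogram(x, ref),
        "shades_of_gray": lambda x: shades_of_gray(x, cfg.minkowski_p),
        "macenko": lambda x: macenko_normalize(x, cfg),
    }
    out = img
    for name in STAGES:
        try:
            out = stage_fns[name](out)
        except Exception as exc:  # noqa: BLE001 - stage attribution contract
            raise StageError(name, exc) from exc
        if stage_log is not None:
            stage_log.append(
                {"stage": name, "channel_means": out.reshape(-1, 3).mean(axis=0).tolist()}
            )
    return out


def preprocess_batch(
    images: list[np.ndarray],
    cfg: PreprocessConfig,
    ref: ReferenceStats,
    skip_on_error: bool = False,
) -> tuple[list[np.ndarray], list[dict]]:
    """Batch wrapper; with ``skip_on_error`` a failing image keeps the output
    of its last successful stage and is flagged in the returned report."""
    outputs, report = [], []
    for i, img in enumerate(images):
        stage_log: list = []
        try:
            out = preprocess(img, cfg, ref, stage_log)
            report.append({"index": i, "ok": True, "stages": [s["stage"] for s in stage_log]})
        except StageError as exc:
            if not skip_on_error:
                raise
            # replay the stages that did succeed to recover their output
            stage_fns = {
                "clahe": lambda x: apply_clahe(x, cfg),
                "histmatch": lambda x: match_histogram(x, ref),
                "shades_of_gray": lambda x: shades_of_gray(x, cfg.minkowski_p),
                "macenko": lambda x: macenko_normalize(x, cfg),
            }
            out = img
            for name in STAGES:
                if name == exc.stage:
                    break
                out = stage_fns[name](out)
            report.append({"index": i, "ok": False, "failed_stage": exc.stage,
                           "stages": [s["stage"] for s in stage_log]})
        outputs.append(out)
    return outputs, report
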