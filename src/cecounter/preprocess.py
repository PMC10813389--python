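"""Preprocessing chain and flip-based augmentation.

Fixed pipeline order: (1) area-interpolation resize (centers scaled by the
same factor), (2) gamma correction, (3) percentile contrast stretch,
(4) unsharp-mask boundary highlighting, (5) optional histogram equalization.
All steps are deterministic and preserve the input dtype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize_local_mean

from .dataset_io import AnnotatedImage

MIN_OUTPUT_DIM = 16
UNSHARP_SIGMA = 2.0

AUGMENT_MODES = ("x2_flip", "x4_flip")


@dataclass(frozen=True)
class PreprocessConfig:
    resize_factor: float = 0.25
    gamma: float = 0.8
    contrast_stretch: tuple[float, float] = (1.0, 99.0)
    boundary_highlight_weight: float = 0.5
    equalize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.resize_factor <= 1.0:
            raise ValueError("resize_factor must be in (0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        lo, hi = self.contrast_stretch
        if not 0.0 <= lo < hi <= 100.0:
            raise ValueError("contrast_stretch must satisfy 0 <= low < high <= 100")
        if self.boundary_highlight_weight < 0:
            raise ValueError("boundary_highlight_weight must be >= 0")


def _equalize(img: np.ndarray) -> np.ndarray:
    """Histogram equalization on [0, 255]; constant images pass through."""
    if img.max() == img.min():
        return img.copy()
    from skimage import exposure

    return exposure.equalize_hist(img / 255.0) * 255.0


def preprocess_image(img: AnnotatedImage, cfg: PreprocessConfig) -> AnnotatedImage:
    """Apply the full chain to one image, remapping its centers through the resize."""
    pixels = np.asarray(img.pixels, dtype=np.float64)
    centers = img.centers.copy()
    um_per_px = img.um_per_px
    f = cfg.resize_factor
    if f != 1.0:
        out_h = int(round(pixels.shape[0] * f))
        out_w = int(round(pixels.shape[1] * f))
        if min(out_h, out_w) < MIN_OUTPUT_DIM:
            raise ValueError(
                f"resize_factor {f} gives {out_w}x{out_h} < {MIN_OUTPUT_DIM} px"
            )
        pixels = resize_local_mean(pixels, (out_h, out_w))
        centers = centers * f
        um_per_px = um_per_px / f

    if cfg.gamma != 1.0:
        pixels = 255.0 * np.power(np.clip(pixels, 0, 255) / 255.0, cfg.gamma)

    lo_pct, hi_pct = cfg.contrast_stretch
    lo, hi = np.percentile(pixels, [lo_pct, hi_pct])
    if hi > lo:
        pixels = np.clip((pixels - lo) / (hi - lo), 0.0, 1.0) * 255.0

    w = cfg.boundary_highlight_weight
    if w > 0:
        blurred = gaussian_filter(pixels, UNSHARP_SIGMA)
        pixels = np.clip(pixels + w * (pixels - blurred), 0.0, 255.0)

    if cfg.equalize:
        pixels = _equalize(pixels)

    if np.issubdtype(np.asarray(img.pixels).dtype, np.integer):
        pixels = np.clip(np.round(pixels), 0, 255).astype(np.asarray(img.pixels).dtype)
    # clamp centers that land exactly on the scaled boundary
    if centers.size:
        centers[:, 0] = np.clip(centers[:, 0], 0, pixels.shape[1] - 1)
        centers[:, 1] = np.clip(centers[:, 1], 0, pixels.shape[0] - 1)
    return img.with_(pixels=pixels, centers=centers, um_per_px=um_per_px)


# ---------------------------------------------------------------------------
# geometric augmentation


def flip_h(rec: AnnotatedImage, suffix: str = "::hflip") -> AnnotatedImage:
    """Horizontal mirror; x -> width-1-x."""
    centers = rec.centers.copy()
    if centers.size:
        centers[:, 0] = rec.width - 1 - centers[:, 0]
    return rec.with_(
        image_id=rec.image_id + suffix, pixels=np.fliplr(rec.pixels), centers=centers
    )


def flip_v(rec: AnnotatedImage, suffix: str = "::vflip") -> AnnotatedImage:
    """Vertical mirror; y -> height-1-y."""
    centers = rec.centers.copy()
    if centers.size:
        centers[:, 1] = rec.height - 1 - centers[:, 1]
    return rec.with_(
        image_id=rec.image_id + suffix, pixels=np.flipud(rec.pixels), centers=centers
    )


def rot180(rec: AnnotatedImage, suffix: str = "::rot180") -> AnnotatedImage:
    centers = rec.centers.copy()
    if centers.size:
        centers[:, 0] = rec.width - 1 - centers[:, 0]
        centers[:, 1] = rec.height - 1 - centers[:, 1]
    return rec.with_(
        image_id=rec.image_id + suffix,
        pixels=np.flipud(np.fliplr(rec.pixels)),
        centers=centers,
    )


def augment(records: Sequence[AnnotatedImage], mode: str = "x2_flip") -> list[AnnotatedImage]:
    """x2_flip: original + horizontal mirror. x4_flip: + vertical mirror + 180deg."""
    if mode not in AUGMENT_MODES:
        raise ValueError(f"mode must be one of {AUGMENT_MODES}, got {mode!r}")
    if len(records) == 0:
        raise ValueError("augment requires a nonempty input")
    out: list[AnnotatedImage] = []
    for rec in records:
        out.append(rec)
        out.append(flip_h(rec))
        if mode == "x4_flip":
            out.append(flip_v(rec))
            out.append(rot180(rec))
    return out
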