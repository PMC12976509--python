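"""Foreground segmentation, sliding-window patch tiling, filtering, sampling.

The scoring pipeline never classifies whole fields: each field is tiled into
112x112 patches on a 100-px stride, patches with less than 50% cell-region
(foreground) coverage are discarded, and small random subsets of the surviving
pool feed the classifier.  Foreground here means the cell footprint, found by
a classical blur/Otsu/morphology segmenter; any externally computed mask
(e.g. from a learned instance segmenter) can be supplied instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

logger = logging.getLogger(__name__)

PATCH_SIZE_DEFAULT = 112
STRIDE_DEFAULT = 100
MIN_FG_DEFAULT = 0.5
SAMPLE_K_DEFAULT = 4


class FieldUnusableError(RuntimeError):
    """No patch survives the foreground filter for this field."""

    def __init__(self, field_id: str = "", message: str | None = None):
        self.field_id = field_id
        super().__init__(message or f"field {field_id!r} has an empty filtered patch pool")


@dataclass
class ForegroundMask:
    """Binary cell-region mask aligned to its field."""

    mask: np.ndarray
    method_tag: str = "classical"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {self.mask.shape}")


@dataclass
class Patch:
    """Square sub-image with its field-coordinate origin and foreground cover."""

    pixels: np.ndarray
    origin_rc: tuple[int, int]
    fg_fraction: float


def segment_foreground(
    image: np.ndarray,
    sigma: float = 8.0,
    min_object_px: int = 2000,
    sensitivity: float = 0.5,
) -> ForegroundMask:
    """Classical cell-region segmentation.

    Gaussian blur(``sigma``) -> Otsu threshold scaled by ``sensitivity`` ->
    morphological closing with a disc of radius ``sigma`` -> drop components
    smaller than ``min_object_px`` -> fill holes.  The blur spreads the
    punctate/tubular mitochondrial signal across the cell body; Otsu on that
    blurred image separates structure cores from everything else, so the
    threshold is halved by default to also capture the faint cytoplasmic rim
    of the cell.  An all-zero (or constant) image yields an empty mask.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"segment_foreground expects a 2D image, got shape {image.shape}")
    blurred = ndimage.gaussian_filter(image, sigma=sigma) if sigma > 0 else image
    if np.ptp(blurred) == 0:
        return ForegroundMask(mask=np.zeros_like(image, dtype=bool))
    thresh = filters.threshold_otsu(blurred) * sensitivity
    binary = blurred > thresh
    if sigma > 0:
        binary = morphology.closing(binary, morphology.disk(int(round(sigma))))
    if min_object_px > 1:
        binary = morphology.remove_small_objects(binary, max_size=min_object_px - 1)
    binary = ndimage.binary_fill_holes(binary)
    return ForegroundMask(mask=binary.astype(bool))


def tile_patches(
    image: np.ndarray,
    mask: ForegroundMask | np.ndarray,
    patch_size: int = PATCH_SIZE_DEFAULT,
    stride: int = STRIDE_DEFAULT,
) -> list[Patch]:
    """All fully-contained sliding-window patches, row-major.

    Origins are ``(i*stride, j*stride)`` for every placement where the patch
    fits entirely inside the field (no partial or padded edge patches); the
    foreground fraction is the mean mask coverage of the window.
    """
    image = np.asarray(image)
    mask_arr = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask).astype(bool)
    if image.shape != mask_arr.shape:
        raise ValueError(f"image {image.shape} and mask {mask_arr.shape} shapes differ")
    h, w = image.shape
    if patch_size > h or patch_size > w:
        raise ValueError(f"patch_size {patch_size} exceeds field dimensions {image.shape}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    patches = []
    for r in range(0, h - patch_size + 1, stride):
        for c in range(0, w - patch_size + 1, stride):
            window_mask = mask_arr[r : r + patch_size, c : c + patch_size]
            patches.append(
                Patch(
                    pixels=image[r : r + patch_size, c : c + patch_size],
                    origin_rc=(r, c),
                    fg_fraction=float(window_mask.mean()),
                )
            )
    return patches


def filter_patches(patches: list[Patch], min_fg: float = MIN_FG_DEFAULT) -> list[Patch]:
    """Keep patches with ``fg_fraction >= min_fg`` (boundary inclusive:
    exactly-half-foreground patches are retained), preserving order."""
    return [p for p in patches if p.fg_fraction >= min_fg]


def sample_patches(
    patches: list[Patch],
    k: int = SAMPLE_K_DEFAULT,
    seed: int | np.random.Generator = 0,
    field_id: str = "",
) -> list[Patch]:
    """Uniformly sample ``k`` patches from the filtered pool.

    Without replacement when the pool has at least ``k`` patches; with
    replacement (and a warning) for sparser pools, so sparse fields still
    score.  Deterministic given the seed.
    """
    if len(patches) == 0:
        raise FieldUnusableError(field_id=field_id)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(patches) >= k:
        idx = rng.choice(len(patches), size=k, replace=False)
    else:
        warnings.warn(
            f"patch pool of {len(patches)} smaller than k={k}"
            + (f" for field {field_id}" if field_id else "")
            + "; sampling with replacement",
            stacklevel=2,
        )
        idx = rng.choice(len(patches), size=k, replace=True)
    return [patches[i] for i in idx]


def patch_pool(
    image: np.ndarray,
    mask: ForegroundMask | np.ndarray,
    patch_size: int = PATCH_SIZE_DEFAULT,
    stride: int = STRIDE_DEFAULT,
    min_fg: float = MIN_FG_DEFAULT,
) -> list[Patch]:
    """tile -> filter in one call; the standard pool construction."""
    return filter_patches(tile_patches(image, mask, patch_size, stride), min_fg)
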