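"""Field/mask/manifest I/O, z-projection and intensity normalization.

Fields are single-channel TIFFs (8- or 16-bit), optionally multi-page
z-stacks; manifests are CSV tables mapping each field to its label,
acquisition batch ("experiment") and optional participant.  All downstream
steps consume a float image normalized to [0, 1] by percentile stretching.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class FormatError(ValueError):
    """Unreadable or unsupported image file."""


MANIFEST_REQUIRED = ("field_id", "path", "label", "experiment_id")
MANIFEST_OPTIONAL = ("participant_id", "phi", "mask_path", "group")


@dataclass
class FluorescenceField:
    """One 2D fluorescence field plus acquisition metadata."""

    image: np.ndarray
    field_id: str = ""
    label: str | None = None
    experiment_id: str = ""
    participant_id: str | None = None
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError(f"field image must be 2D, got shape {self.image.shape}")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("field image contains non-finite pixels")
        if self.image.min() < 0:
            raise ValueError("field image contains negative pixels")


def read_field(path: str | Path) -> np.ndarray:
    """Read a TIFF field; returns a 2D array or an (n_slices, H, W) stack.

    RGB/multi-channel images are rejected — the pipeline is single-channel.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # truncated / not a TIFF
        raise FormatError(f"could not read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < arr.shape[0]:
        raise FormatError(f"RGB input is unsupported (single-channel expected): {path}")
    if arr.ndim not in (2, 3):
        raise FormatError(f"expected 2D image or 3D stack, got shape {arr.shape}: {path}")
    return arr


def write_field(image: np.ndarray, path: str | Path) -> None:
    """Write an image (or stack) as single-channel TIFF; round-trips pixel
    values exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image), photometric="minisblack")


def max_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum across z; a single 2D slice is returned unchanged."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError(f"expected a non-empty (n, H, W) stack, got shape {stack.shape}")
    return stack.max(axis=0)


def mean_project(stack: np.ndarray) -> np.ndarray:
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError(f"expected a non-empty (n, H, W) stack, got shape {stack.shape}")
    return stack.mean(axis=0)


def normalize_percentile(image: np.ndarray, p_lo: float = 1.0, p_hi: float = 99.0) -> np.ndarray:
    """Affine rescale so the p_lo percentile maps to 0 and p_hi to 1, clipped.

    A constant image maps to all zeros.  Replaces whatever intensity
    calibration the acquisition software applied; runs before patching and
    before morphometry thresholding.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("normalize_percentile: non-finite pixels")
    if not p_lo < p_hi:
        raise ValueError(f"require p_lo < p_hi, got {p_lo} >= {p_hi}")
    lo, hi = np.percentile(image, [p_lo, p_hi])
    if hi <= lo:
        return np.zeros_like(image)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def load_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Read a manifest CSV and validate columns; relative image paths are
    resolved against the manifest's directory."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"field_id": str, "experiment_id": str}, keep_default_na=False)
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing required columns: {missing}")
    if df["field_id"].duplicated().any():
        dups = df.loc[df["field_id"].duplicated(), "field_id"].tolist()
        raise ValueError(f"duplicate field_id in manifest: {dups}")
    root = path.parent
    for col in ("path", "mask_path"):
        if col in df.columns:
            df[col] = [str((root / p)) if p and not Path(p).is_absolute() else p for p in df[col]]
            if check_paths:
                missing_files = [p for p in df[col] if p and not Path(p).exists()]
                if missing_files:
                    raise FileNotFoundError(f"manifest references missing files: {missing_files[:5]}")
    return df


def save_manifest(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
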