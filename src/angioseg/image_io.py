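"""Grayscale image and binary mask I/O, plus config/report file helpers.

Images are held as float64 arrays on the 0-255 scale with 0-based
(row, col) indexing; masks are boolean arrays of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

__all__ = [
    "GrayImage",
    "BinaryMask",
    "read_gray_image",
    "read_mask",
    "write_gray_image",
    "write_mask",
    "write_label_map",
    "load_config",
    "save_config",
    "write_report_csv",
]

#: threshold used to binarize 8-bit mask files (midpoint of the range)
MASK_THRESHOLD = 127.5


@dataclass(frozen=True)
class GrayImage:
    """A 2D grayscale image with intensities in [0, 255]."""

    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 2:
            raise ValidationError(f"expected a 2D array, got ndim={arr.ndim}")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValidationError(f"image too small: {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("image contains non-finite intensities")
        if arr.min() < 0 or arr.max() > 255:
            raise ValidationError(
                f"intensities outside [0, 255]: [{arr.min()}, {arr.max()}]"
            )
        object.__setattr__(self, "data", arr)

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "GrayImage":
        return cls(np.asarray(arr, dtype=np.float64))


@dataclass(frozen=True)
class BinaryMask:
    """A boolean in-region/background mask paired with a GrayImage shape."""

    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.dtype != np.bool_:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValidationError("mask values must be two-valued (0/1)")
            arr = arr.astype(bool)
        if arr.ndim != 2:
            raise ValidationError(f"expected a 2D mask, got ndim={arr.ndim}")
        object.__setattr__(self, "data", arr)

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def count(self) -> int:
        """Number of in-region pixels."""
        return int(self.data.sum())

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "BinaryMask":
        return cls(np.asarray(arr))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool(np.all(self.data == other.data))


def _to_gray_array(raw: np.ndarray) -> np.ndarray:
    """Collapse channels and rescale to the 0-255 range."""
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr.mean(axis=2)
    arr = arr.astype(np.float64)
    if raw.dtype == np.uint16:
        arr *= 255.0 / 65535.0
    elif raw.dtype == np.bool_:
        arr *= 255.0
    return arr


def read_gray_image(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF/JPEG file as a grayscale image.

    Multi-channel inputs are converted by averaging the color channels,
    so an already-gray RGB image maps onto its single channel exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = iio.imread(path)
    if raw.size == 0:
        raise ValidationError(f"zero-area image: {path}")
    return GrayImage(_to_gray_array(raw))


def read_mask(path: str | Path, threshold: float | None = None) -> BinaryMask:
    """Read an image file as a binary mask (nonzero -> in-region).

    Files with more than two distinct raw values are rejected unless an
    explicit ``threshold`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _to_gray_array(iio.imread(path))
    if threshold is None:
        if np.unique(arr).size > 2:
            raise ValidationError(
                f"{path} has more than two distinct values; pass a threshold"
            )
        threshold = MASK_THRESHOLD
    return BinaryMask(arr > threshold)


def write_gray_image(image: GrayImage, path: str | Path) -> None:
    """Write an image as 8-bit PNG (intensities rounded to integers)."""
    arr = np.rint(image.data).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG with values 0/255 (lossless round trip)."""
    arr = np.where(mask.data, 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label map as an 8-bit PNG (label = pixel value)."""
    arr = np.asarray(labels)
    if arr.max(initial=0) > 255:
        raise ValidationError("more than 255 labels cannot be stored as 8-bit PNG")
    iio.imwrite(Path(path), arr.astype(np.uint8))


def load_config(path: str | Path) -> dict:
    """Load a flat key-value YAML configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"config file {path} must hold a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_report_csv(rows: list[dict], path: str | Path) -> None:
    """Write evaluation report rows (one per image pair) as CSV."""
    pd.DataFrame(rows).to_csv(path, index=False)
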