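"""Synthetic angiography-like phantoms with exact ground-truth masks.

A phantom has a smooth background with a linear horizontal gradient,
brighter curvilinear vessel-like random walks, a dark elliptical target
region (the ground truth), and additive Gaussian noise.  Everything is
deterministic given the spec's RNG seed, and images are rounded to
integer gray levels so PNG round trips are lossless.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .image_io import BinaryMask, GrayImage, write_gray_image, write_mask

__all__ = ["PhantomSpec", "make_phantom", "make_gaussian_field", "make_batch"]


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 250
    width: int = 250
    target_center: tuple[float, float] = (125.0, 125.0)  # (row, col)
    target_axes: tuple[float, float] = (55.0, 40.0)  # semi-axes (col, row dir)
    target_rotation: float = 0.0  # degrees
    target_intensity: float = 60.0
    vessel_count: int = 3
    vessel_width: tuple[float, float] = (2.0, 4.0)
    vessel_intensity: float = 230.0
    background: float = 180.0
    gradient: float = 20.0  # +/- amplitude across the width
    noise_sd: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValidationError("phantom must be at least 2x2")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for v in (self.target_intensity, self.vessel_intensity, self.background):
            if not 0 <= v <= 255:
                raise ValidationError(f"intensity {v} outside [0, 255]")
        # rotated-ellipse bounding half-extents must stay inside the frame
        theta = math.radians(self.target_rotation)
        a, b = self.target_axes
        ext_c = math.hypot(a * math.cos(theta), b * math.sin(theta))
        ext_r = math.hypot(a * math.sin(theta), b * math.cos(theta))
        r0, c0 = self.target_center
        if (
            r0 - ext_r < 0
            or r0 + ext_r > self.height - 1
            or c0 - ext_c < 0
            or c0 + ext_c > self.width - 1
        ):
            raise ValidationError("target ellipse extends outside the image")


def _ellipse_mask(spec: PhantomSpec) -> np.ndarray:
    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width]
    theta = math.radians(spec.target_rotation)
    r0, c0 = spec.target_center
    a, b = spec.target_axes
    x = (cc - c0) * math.cos(theta) + (rr - r0) * math.sin(theta)
    y = -(cc - c0) * math.sin(theta) + (rr - r0) * math.cos(theta)
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


def _draw_vessels(img: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> None:
    h, w = img.shape
    n_steps = int(1.5 * (h + w))
    for _ in range(spec.vessel_count):
        # start on a random border pixel heading inward
        side = rng.integers(4)
        if side == 0:
            r, c, ang = 0.0, float(rng.uniform(0, w - 1)), math.pi / 2
        elif side == 1:
            r, c, ang = float(h - 1), float(rng.uniform(0, w - 1)), -math.pi / 2
        elif side == 2:
            r, c, ang = float(rng.uniform(0, h - 1)), 0.0, 0.0
        else:
            r, c, ang = float(rng.uniform(0, h - 1)), float(w - 1), math.pi
        ang += rng.uniform(-0.5, 0.5)
        radius = rng.uniform(*spec.vessel_width) / 2.0
        rad_i = max(1, int(math.ceil(radius)))
        for _ in range(n_steps):
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < h and 0 <= ci < w):
                break
            lo_r, hi_r = max(0, ri - rad_i), min(h, ri + rad_i + 1)
            lo_c, hi_c = max(0, ci - rad_i), min(w, ci + rad_i + 1)
            sub_r, sub_c = np.mgrid[lo_r:hi_r, lo_c:hi_c]
            disk = (sub_r - r) ** 2 + (sub_c - c) ** 2 <= radius**2
            img[lo_r:hi_r, lo_c:hi_c][disk] = spec.vessel_intensity
            ang += rng.normal(0.0, 0.12)
            r += math.sin(ang)
            c += math.cos(ang)


def make_phantom(spec: PhantomSpec) -> tuple[GrayImage, BinaryMask]:
    """Render a phantom image and its exact target-ellipse ground truth."""
    rng = np.random.default_rng(spec.rng_seed)
    cols = np.linspace(-1.0, 1.0, spec.width)
    img = np.broadcast_to(
        spec.background + spec.gradient * cols, (spec.height, spec.width)
    ).copy()
    _draw_vessels(img, spec, rng)
    mask = _ellipse_mask(spec)
    img[mask] = spec.target_intensity
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.rint(np.clip(img, 0.0, 255.0))
    return GrayImage(img), BinaryMask(mask)


def make_gaussian_field(n: int, mu: float, sd: float, rng_seed: int) -> np.ndarray:
    """n independent Normal(mu, sd) draws, unclipped."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    return np.random.default_rng(rng_seed).normal(mu, sd, size=n)


def make_batch(specs: list[PhantomSpec], out_dir: str | Path) -> pd.DataFrame:
    """Write image/mask PNG pairs plus a manifest CSV; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(specs):
        pid = f"phantom_{i:03d}"
        image, mask = make_phantom(spec)
        image_path = out_dir / f"{pid}.png"
        mask_path = out_dir / f"{pid}_mask.png"
        write_gray_image(image, image_path)
        write_mask(mask, mask_path)
        row = {"id": pid, "image": str(image_path), "mask": str(mask_path)}
        row.update({k: str(v) for k, v in asdict(spec).items()})
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
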