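"""Seeded region growing on an 8-connected pixel lattice.

A region starts from a seed pixel and absorbs frontier neighbors that
pass the active similarity criterion against the region's *current*
statistics; the running mean and standard deviation are updated online
(Welford recurrence, equivalent to the sample-variance recurrence

    sigma_N^2 = [(N-2) sigma_{N-1}^2 + (N/(N-1)) (I_N - mu_N)^2] / (N-1)

) immediately on every acceptance.  Growth is breadth-first with a FIFO
frontier and neighbors pushed in row-major offset order, which makes the
result fully deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .image_io import BinaryMask, GrayImage

__all__ = [
    "RegionStats",
    "GrowthConfig",
    "update_region_stats",
    "sd_criterion",
    "mean_criterion",
    "grow_region",
    "grow_all",
]

logger = logging.getLogger(__name__)

#: 8-neighborhood offsets in row-major order from the top-left
_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass(frozen=True)
class RegionStats:
    """Running count, mean and standard deviation of a growing region.

    ``sigma`` is the sample standard deviation (denominator N-1); it is 0
    for N <= 1.  ``m2`` is the internal sum of squared deviations kept so
    updates are numerically stable.
    """

    n: int = 0
    mu: float = math.nan
    m2: float = 0.0

    @property
    def is_empty(self) -> bool:
        return self.n == 0

    @property
    def sigma(self) -> float:
        if self.n < 2:
            return 0.0
        return math.sqrt(self.m2 / (self.n - 1))

    def push(self, intensity: float) -> "RegionStats":
        """Stats for the accepted-intensity sequence extended by one value."""
        x = float(intensity)
        if not math.isfinite(x):
            raise ValidationError(f"non-finite intensity: {x}")
        if self.n == 0:
            return RegionStats(n=1, mu=x, m2=0.0)
        n = self.n + 1
        delta = x - self.mu
        mu = self.mu + delta / n
        m2 = self.m2 + delta * (x - mu)
        return RegionStats(n=n, mu=mu, m2=m2)


def update_region_stats(stats: RegionStats, intensity: float) -> RegionStats:
    """Functional form of :meth:`RegionStats.push`."""
    return stats.push(intensity)


@dataclass(frozen=True)
class GrowthConfig:
    """Region-growing criterion parameters.

    ``x_sd`` is the weighting parameter of the mu +/- X*sigma window;
    ``x_mean`` is the half-width (in gray levels) of the mean-window
    criterion and defaults to ``x_sd`` when left as None.  ``sigma_floor``
    keeps the sd-window open while the region's own spread is still
    tiny (a fresh region has sigma = 0, under which the strict window
    admits nothing).
    """

    x_sd: float = 3.0
    x_mean: float | None = None
    criterion_mode: str = "both"  # one of {"sd", "mean", "both"}
    connectivity: int = 8
    max_region_fraction: float = 0.9
    sigma_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.x_sd <= 0:
            raise ValidationError(f"x_sd must be > 0, got {self.x_sd}")
        if self.x_mean is not None and self.x_mean <= 0:
            raise ValidationError(f"x_mean must be > 0, got {self.x_mean}")
        if self.criterion_mode not in ("sd", "mean", "both"):
            raise ValidationError(f"unknown criterion_mode: {self.criterion_mode}")
        if self.connectivity != 8:
            raise ValidationError("only 8-connectivity is supported")
        if not 0 < self.max_region_fraction <= 1:
            raise ValidationError("max_region_fraction must be in (0, 1]")
        if self.sigma_floor < 0:
            raise ValidationError("sigma_floor must be >= 0")

    @property
    def effective_x_mean(self) -> float:
        return self.x_sd if self.x_mean is None else self.x_mean


def sd_criterion(stats: RegionStats, intensity, x: float, sigma_floor: float = 0.0):
    """Accept iff mu - X*s < intensity < mu + X*s with s = max(sigma, floor).

    Inequalities are strict.  ``intensity`` may be a scalar or an array
    (vectorized evaluation against fixed stats).
    """
    if stats.is_empty:
        raise ValidationError("sd_criterion requires nonempty region stats")
    s = max(stats.sigma, sigma_floor)
    i = np.asarray(intensity, dtype=np.float64)
    out = (stats.mu - x * s < i) & (i < stats.mu + x * s)
    return bool(out) if out.ndim == 0 else out


def mean_criterion(stats: RegionStats, intensity, x: float):
    """Accept iff |intensity - mu| < x (strict)."""
    if stats.is_empty:
        raise ValidationError("mean_criterion requires nonempty region stats")
    i = np.asarray(intensity, dtype=np.float64)
    out = np.abs(i - stats.mu) < x
    return bool(out) if out.ndim == 0 else out


def _grow_kernel(img, labels, seed_r, seed_c, label, x_sd, x_mean, use_sd, use_mean, sigma_floor, cap):
    """BFS growth from one seed, writing ``label`` into ``labels``.

    Pixels already labeled (by this or an earlier region) are never
    reassigned or traversed.  Returns (n, mean, m2) of the grown region.
    """
    h, w = img.shape
    qr = np.empty(8 * h * w + 8, np.int64)
    qc = np.empty(8 * h * w + 8, np.int64)
    head = 0
    tail = 0
    labels[seed_r, seed_c] = label
    n = 1
    mean = img[seed_r, seed_c]
    m2 = 0.0
    for k in range(8):
        rr = seed_r + _OFF_R[k]
        cc = seed_c + _OFF_C[k]
        if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] == 0:
            qr[tail] = rr
            qc[tail] = cc
            tail += 1
    while head < tail and n < cap:
        r = qr[head]
        c = qc[head]
        head += 1
        if labels[r, c] != 0:
            continue
        x = img[r, c]
        if n >= 2:
            sigma = math.sqrt(m2 / (n - 1))
        else:
            sigma = 0.0
        if sigma < sigma_floor:
            sigma = sigma_floor
        ok = True
        if use_sd:
            ok = (mean - x_sd * sigma < x) and (x < mean + x_sd * sigma)
        if ok and use_mean:
            ok = (mean - x_mean < x) and (x < mean + x_mean)
        if not ok:
            continue
        labels[r, c] = label
        n += 1
        delta = x - mean
        mean += delta / n
        m2 += delta * (x - mean)
        for k in range(8):
            rr = r + _OFF_R[k]
            cc = c + _OFF_C[k]
            if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] == 0:
                qr[tail] = rr
                qc[tail] = cc
                tail += 1
    return n, mean, m2


_OFF_R = np.array([o[0] for o in _OFFSETS], dtype=np.int64)
_OFF_C = np.array([o[1] for o in _OFFSETS], dtype=np.int64)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _grow_kernel = njit(cache=False)(_grow_kernel)
except ImportError:  # pragma: no cover
    pass


def _check_seed(image: GrayImage, seed: tuple[int, int]) -> tuple[int, int]:
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < image.height and 0 <= c < image.width):
        raise ValidationError(f"seed {seed} outside image bounds {image.shape}")
    return r, c


def _cap(image: GrayImage, config: GrowthConfig) -> int:
    return max(1, int(math.floor(config.max_region_fraction * image.height * image.width)))


def grow_region(
    image: GrayImage, seed: tuple[int, int], config: GrowthConfig | None = None
) -> tuple[BinaryMask, RegionStats]:
    """Grow a single region from ``seed``; the seed is always accepted."""
    config = config or GrowthConfig()
    r, c = _check_seed(image, seed)
    labels = np.zeros(image.shape, dtype=np.int32)
    n, mean, m2 = _grow_kernel(
        image.data,
        labels,
        r,
        c,
        1,
        float(config.x_sd),
        float(config.effective_x_mean),
        config.criterion_mode in ("sd", "both"),
        config.criterion_mode in ("mean", "both"),
        float(config.sigma_floor),
        _cap(image, config),
    )
    return BinaryMask(labels == 1), RegionStats(n=int(n), mu=float(mean), m2=float(m2))


def grow_all(
    image: GrayImage,
    seeds: list[tuple[int, int]],
    config: GrowthConfig | None = None,
) -> tuple[np.ndarray, list[RegionStats]]:
    """Grow regions sequentially in seed order under a first-claim rule.

    Returns a label map (0 = background, i+1 = region of seed i) and the
    per-region stats.  A seed falling inside an already-grown region is
    skipped (its region stays empty) with a logged notice.
    """
    config = config or GrowthConfig()
    labels = np.zeros(image.shape, dtype=np.int32)
    stats: list[RegionStats] = []
    cap = _cap(image, config)
    for i, seed in enumerate(seeds):
        r, c = _check_seed(image, seed)
        if labels[r, c] != 0:
            logger.info("seed %s already claimed by region %d; skipped", seed, labels[r, c])
            stats.append(RegionStats())
            continue
        n, mean, m2 = _grow_kernel(
            image.data,
            labels,
            r,
            c,
            i + 1,
            float(config.x_sd),
            float(config.effective_x_mean),
            config.criterion_mode in ("sd", "both"),
            config.criterion_mode in ("mean", "both"),
            float(config.sigma_floor),
            cap,
        )
        stats.append(RegionStats(n=int(n), mu=float(mean), m2=float(m2)))
    return labels, stats
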