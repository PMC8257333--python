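"""Fuzzy C-means clustering of image intensities.

The clustering operates on scalar intensities only.  Memberships follow
the standard inverse-distance-ratio update with exponent ``t = 2/(m-1)``
where ``m`` is the fuzzifier, and cluster centers are membership-weighted
means with the memberships raised to the fuzzifier.  The alternating
optimization minimizes

    E = sum_k sum_i mem_ki^m * (center_k - pixel_i)^2

which is the objective whose stationary points are exactly those updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .image_io import GrayImage

__all__ = [
    "FCMParams",
    "FCMResult",
    "init_centers",
    "update_memberships",
    "update_centers",
    "fcm_objective",
    "run_fcm",
    "defuzzify",
]


@dataclass(frozen=True)
class FCMParams:
    """Hyperparameters for a fuzzy C-means run."""

    n_clusters: int = 6
    fuzzifier: float = 2.0
    tol: float = 1e-4
    max_iter: int = 300
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValidationError(f"n_clusters must be >= 1, got {self.n_clusters}")
        if self.fuzzifier <= 1:
            raise ValidationError(f"fuzzifier must be > 1, got {self.fuzzifier}")
        if self.max_iter < 1:
            raise ValidationError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.tol < 0:
            raise ValidationError(f"tol must be >= 0, got {self.tol}")


@dataclass(frozen=True)
class FCMResult:
    """Outcome of :func:`run_fcm`.

    ``memberships`` has shape (K, N) with columns summing to 1, where N
    is the number of pixels flattened in row-major order from ``shape``.
    """

    centers: np.ndarray = field(repr=False)
    memberships: np.ndarray = field(repr=False)
    objective_trace: np.ndarray = field(repr=False)
    iterations: int = 0
    shape: tuple[int, int] = (0, 0)


def _flat(image: GrayImage | np.ndarray) -> np.ndarray:
    data = image.data if isinstance(image, GrayImage) else np.asarray(image, float)
    return data.ravel()


def init_centers(image: GrayImage, params: FCMParams) -> np.ndarray:
    """Pick K distinct starting centers spread over the intensity range.

    Centers are data quantiles; duplicates (too few distinct intensities
    for K quantiles) fall back to seeded jittered quantiles so the
    returned centers are always pairwise distinct.
    """
    x = _flat(image)
    k = params.n_clusters
    rng = np.random.default_rng(params.rng_seed)
    qs = (np.arange(k) + 0.5) / k
    centers = np.quantile(x, qs)
    lo, hi = float(x.min()), float(x.max())
    span = max(hi - lo, 1.0)
    for _ in range(100):
        if np.unique(centers).size == k:
            return np.sort(centers)
        centers = np.quantile(x, qs) + rng.uniform(-0.01, 0.01, size=k) * span
    # pathological ties: jittered linspace over the full range
    centers = np.linspace(lo, hi, k) + rng.uniform(-0.01, 0.01, size=k) * span
    return np.sort(centers)


def update_memberships(
    image: GrayImage | np.ndarray, centers: np.ndarray, params: FCMParams
) -> np.ndarray:
    """Inverse-distance membership update.

    mem_ki = 1 / sum_j (|pixel_i - center_k| / |pixel_i - center_j|)^t
    with t = 2/(fuzzifier - 1).  A pixel coinciding with a center gets
    membership 1 on the nearest coincident center (lowest index on ties).
    """
    x = _flat(image)
    c = np.asarray(centers, dtype=np.float64)
    t = 2.0 / (params.fuzzifier - 1.0)
    d = np.abs(c[:, None] - x[None, :])  # (K, N)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv = d ** (-t)
        mem = inv / inv.sum(axis=0)
    # coincident pixel/center (or overflow at tiny distances): crisp
    # assignment to the nearest center, lowest index on ties
    bad = (d == 0).any(axis=0) | ~np.isfinite(mem).all(axis=0)
    if bad.any():
        cols = np.nonzero(bad)[0]
        mem[:, cols] = 0.0
        mem[np.argmin(d[:, cols], axis=0), cols] = 1.0
    return mem


def update_centers(
    image: GrayImage | np.ndarray, memberships: np.ndarray, params: FCMParams
) -> np.ndarray:
    """center_k = sum_i mem_ki^m * pixel_i / sum_i mem_ki^m."""
    x = _flat(image)
    w = memberships**params.fuzzifier
    denom = w.sum(axis=1)
    if np.any(denom == 0):
        raise RuntimeError("membership column collapsed to zero weight")
    return (w @ x) / denom


def fcm_objective(
    image: GrayImage | np.ndarray,
    centers: np.ndarray,
    memberships: np.ndarray,
    params: FCMParams,
) -> float:
    """Weighted within-cluster sum of squared intensity distances."""
    x = _flat(image)
    c = np.asarray(centers, dtype=np.float64)
    w = memberships**params.fuzzifier
    sq = (c[:, None] - x[None, :]) ** 2
    return float(np.sum(w * sq))


def run_fcm(image: GrayImage, params: FCMParams) -> FCMResult:
    """Alternate membership and center updates until the maximum absolute
    center shift drops below ``tol`` or ``max_iter`` is reached."""
    x = _flat(image)
    if not np.all(np.isfinite(x)):
        raise ValidationError("image contains non-finite intensities")
    centers = init_centers(image, params)
    trace = []
    mem = update_memberships(x, centers, params)
    iterations = 0
    for iterations in range(1, params.max_iter + 1):
        # a cluster whose memberships collapsed to zero (coincident
        # centers on degenerate data) keeps its previous center
        w = mem**params.fuzzifier
        denom = w.sum(axis=1)
        live = denom > 0
        new_centers = centers.copy()
        new_centers[live] = (w[live] @ x) / denom[live]
        trace.append(fcm_objective(x, new_centers, mem, params))
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        mem = update_memberships(x, centers, params)
        if shift < params.tol:
            break
    return FCMResult(
        centers=centers,
        memberships=mem,
        objective_trace=np.asarray(trace),
        iterations=iterations,
        shape=image.shape,
    )


def defuzzify(memberships: np.ndarray) -> np.ndarray:
    """Hard labels: argmax over clusters, ties broken toward the lowest index."""
    return np.argmax(memberships, axis=0)
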