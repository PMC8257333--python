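"""Evolutionary search over seed configurations for region growing.

A chromosome is a variable-length list of seed coordinates.  Its cost is
how well the regions grown from those seeds reproduce a tri-class
(dark / mid / bright) reference decomposition of the image obtained from
fuzzy clustering:

    cost = [ (GM - I1)^2 + (WM - I2)^2 + (BM - I3)^2 ] / N

summed over pixels, where GM/WM/BM hold the original intensities on the
mid/bright/dark reference tiers and I1/I2/I3 are the analogous images
assembled from the grown regions (each region assigned to a tier by its
mean intensity).  Division by the pixel count N makes costs comparable
across image sizes without changing the argmin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .fcm import FCMResult, defuzzify
from .image_io import GrayImage
from .region_growing import GrowthConfig, grow_all

__all__ = [
    "SeedChromosome",
    "GAConfig",
    "TriClassReference",
    "build_reference",
    "tier_images",
    "chromosome_cost",
    "mutate",
    "crossover",
    "run_ga",
]

#: tier codes
DARK, MID, BRIGHT = 0, 1, 2

#: coordinate jitter half-width used by mutation
_JITTER = 5


@dataclass
class SeedChromosome:
    """GA individual: an ordered list of (row, col) seeds plus cached cost."""

    seeds: list[tuple[int, int]]
    fitness: float | None = None

    def copy(self) -> "SeedChromosome":
        return SeedChromosome(seeds=list(self.seeds), fitness=self.fitness)

    def validate(self, shape: tuple[int, int], n_max: int) -> None:
        if not 1 <= len(self.seeds) <= n_max:
            raise ValidationError(f"chromosome length {len(self.seeds)} out of bounds")
        for r, c in self.seeds:
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValidationError(f"seed ({r}, {c}) outside image {shape}")


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 20
    mutation_rate: float = 0.2
    n_generations: int = 50
    elitism: int = 1
    n_min: int = 1
    n_max: int = 10
    rng_seed: int = 0
    tournament_size: int = 3
    stall_generations: int = 15

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        if not 0 <= self.mutation_rate <= 1:
            raise ValidationError("mutation_rate must be in [0, 1]")
        if self.elitism < 1:
            raise ValidationError("elitism must be >= 1")
        if not 1 <= self.n_min <= self.n_max:
            raise ValidationError("need 1 <= n_min <= n_max")


@dataclass(frozen=True)
class TriClassReference:
    """Dark/mid/bright reference images plus the tier mean-intensity cuts.

    ``bm``/``gm``/``wm`` hold the original intensity on pixels whose
    cluster falls in the dark/mid/bright tier respectively, 0 elsewhere.
    A region is assigned to the tier whose centroid (mean of that tier's
    cluster centers) is nearest the region's mean intensity, so
    ``low_cut``/``high_cut`` are the midpoints between adjacent tier
    centroids: mean below ``low_cut`` -> dark, above ``high_cut`` ->
    bright, otherwise mid.
    """

    gm: np.ndarray = field(repr=False)
    wm: np.ndarray = field(repr=False)
    bm: np.ndarray = field(repr=False)
    low_cut: float = 0.0
    high_cut: float = 0.0

    def classify(self, mean_intensity: float) -> int:
        if mean_intensity < self.low_cut:
            return DARK
        if mean_intensity > self.high_cut:
            return BRIGHT
        return MID


def build_reference(image: GrayImage, fcm_result: FCMResult) -> TriClassReference:
    """Group the K clusters (sorted by center) into three intensity tiers.

    The darkest third of the clusters forms the dark tier, the middle
    third the mid tier and the brightest third the bright tier; region
    classification cuts are midpoints between adjacent tier centroids.
    """
    k = len(fcm_result.centers)
    if k < 3:
        raise ValidationError(f"need at least 3 clusters to build tiers, got {k}")
    order = np.argsort(fcm_result.centers, kind="stable")
    groups = np.array_split(order, 3)
    tier_of_cluster = np.empty(k, dtype=np.int64)
    for tier, grp in enumerate(groups):
        tier_of_cluster[grp] = tier
    centers = np.asarray(fcm_result.centers)
    centroids = [float(centers[grp].mean()) for grp in groups]
    low_cut = (centroids[0] + centroids[1]) / 2.0
    high_cut = (centroids[1] + centroids[2]) / 2.0
    labels = defuzzify(fcm_result.memberships).reshape(image.shape)
    tier_map = tier_of_cluster[labels]
    img = image.data
    bm = np.where(tier_map == DARK, img, 0.0)
    gm = np.where(tier_map == MID, img, 0.0)
    wm = np.where(tier_map == BRIGHT, img, 0.0)
    return TriClassReference(gm=gm, wm=wm, bm=bm, low_cut=low_cut, high_cut=high_cut)


def tier_images(
    image: GrayImage,
    labels: np.ndarray,
    reference: TriClassReference,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split grown regions into (I1 mid, I2 bright, I3 dark) images.

    Each labeled region is assigned to one tier by its mean intensity;
    the returned images carry the original intensity on that tier's
    pixels and 0 elsewhere.
    """
    img = image.data
    i1 = np.zeros_like(img)
    i2 = np.zeros_like(img)
    i3 = np.zeros_like(img)
    n_labels = int(labels.max())
    if n_labels == 0:
        return i1, i2, i3
    flat = labels.ravel()
    sums = np.bincount(flat, weights=img.ravel(), minlength=n_labels + 1)
    counts = np.bincount(flat, minlength=n_labels + 1)
    outs = {DARK: i3, MID: i1, BRIGHT: i2}
    for lab in range(1, n_labels + 1):
        if counts[lab] == 0:
            continue
        tier = reference.classify(sums[lab] / counts[lab])
        sel = labels == lab
        outs[tier][sel] = img[sel]
    return i1, i2, i3


def chromosome_cost(
    chrom: SeedChromosome,
    image: GrayImage,
    reference: TriClassReference,
    growth_config: GrowthConfig | None = None,
) -> float:
    """Per-pixel-normalized squared tri-class mismatch of the grown regions."""
    labels, _ = grow_all(image, chrom.seeds, growth_config)
    i1, i2, i3 = tier_images(image, labels, reference)
    sq = (reference.gm - i1) ** 2 + (reference.wm - i2) ** 2 + (reference.bm - i3) ** 2
    return float(sq.sum() / image.data.size)


def _random_seed(rng: np.random.Generator, shape: tuple[int, int]) -> tuple[int, int]:
    return int(rng.integers(shape[0])), int(rng.integers(shape[1]))


def mutate(
    chrom: SeedChromosome,
    config: GAConfig,
    rng: np.random.Generator,
    shape: tuple[int, int],
) -> SeedChromosome:
    """Jitter each seed w.p. ``mutation_rate``; insert or delete one seed
    w.p. ``mutation_rate`` per chromosome, respecting [n_min, n_max]."""
    seeds = []
    for r, c in chrom.seeds:
        if rng.random() < config.mutation_rate:
            dr, dc = rng.integers(-_JITTER, _JITTER + 1, size=2)
            r = int(np.clip(r + dr, 0, shape[0] - 1))
            c = int(np.clip(c + dc, 0, shape[1] - 1))
        seeds.append((r, c))
    if rng.random() < config.mutation_rate:
        insert = bool(rng.integers(2))
        if insert and len(seeds) >= config.n_max:
            insert = False
        elif not insert and len(seeds) <= config.n_min:
            insert = True
        if insert and len(seeds) < config.n_max:
            seeds.insert(int(rng.integers(len(seeds) + 1)), _random_seed(rng, shape))
        elif not insert and len(seeds) > config.n_min:
            seeds.pop(int(rng.integers(len(seeds))))
    return SeedChromosome(seeds=seeds)


def crossover(
    parent_a: SeedChromosome,
    parent_b: SeedChromosome,
    rng: np.random.Generator,
    config: GAConfig | None = None,
) -> tuple[SeedChromosome, SeedChromosome]:
    """One-point crossover with independent cut points per parent.

    Offspring lengths may change; they are re-clipped into
    [n_min, n_max] (truncated from the tail, or padded from the parents'
    pooled seeds when a cut combination would fall below n_min).
    """
    config = config or GAConfig()
    a, b = parent_a.seeds, parent_b.seeds
    cut_a = int(rng.integers(len(a) + 1))
    cut_b = int(rng.integers(len(b) + 1))
    pool = a + b
    children = []
    for seeds in (a[:cut_a] + b[cut_b:], b[:cut_b] + a[cut_a:]):
        seeds = seeds[: config.n_max]
        i = 0
        while len(seeds) < config.n_min:
            seeds = seeds + [pool[i % len(pool)]]
            i += 1
        children.append(SeedChromosome(seeds=seeds))
    return children[0], children[1]


def _tournament(
    pop: list[SeedChromosome], rng: np.random.Generator, k: int
) -> SeedChromosome:
    idx = rng.integers(len(pop), size=k)
    return min((pop[i] for i in idx), key=lambda ch: ch.fitness)


def run_ga(
    image: GrayImage,
    reference: TriClassReference,
    ga_config: GAConfig | None = None,
    growth_config: GrowthConfig | None = None,
) -> tuple[SeedChromosome, np.ndarray]:
    """Elitist generational GA over seed chromosomes.

    Returns the best-ever chromosome and the best-cost history (one
    entry for the initial population plus one per generation).  With
    ``elitism >= 1`` the history is monotonically non-increasing.  Runs
    stop early after ``stall_generations`` generations without
    improvement of the best cost.
    """
    ga_config = ga_config or GAConfig()
    growth_config = growth_config or GrowthConfig()
    rng = np.random.default_rng(ga_config.rng_seed)
    shape = image.shape

    def evaluate(ch: SeedChromosome) -> SeedChromosome:
        if ch.fitness is None:
            ch.fitness = chromosome_cost(ch, image, reference, growth_config)
        return ch

    pop = []
    for _ in range(ga_config.population_size):
        length = int(rng.integers(ga_config.n_min, ga_config.n_max + 1))
        seeds = [_random_seed(rng, shape) for _ in range(length)]
        pop.append(evaluate(SeedChromosome(seeds=seeds)))

    best = min(pop, key=lambda ch: ch.fitness).copy()
    history = [best.fitness]
    stall = 0
    for _ in range(ga_config.n_generations):
        pop.sort(key=lambda ch: ch.fitness)
        nxt = [pop[i].copy() for i in range(ga_config.elitism)]
        while len(nxt) < ga_config.population_size:
            p1 = _tournament(pop, rng, ga_config.tournament_size)
            p2 = _tournament(pop, rng, ga_config.tournament_size)
            c1, c2 = crossover(p1, p2, rng, ga_config)
            nxt.append(mutate(c1, ga_config, rng, shape))
            if len(nxt) < ga_config.population_size:
                nxt.append(mutate(c2, ga_config, rng, shape))
        pop = [evaluate(ch) for ch in nxt]
        gen_best = min(pop, key=lambda ch: ch.fitness)
        if gen_best.fitness < best.fitness:
            best = gen_best.copy()
            stall = 0
        else:
            stall += 1
        history.append(best.fitness)
        if ga_config.stall_generations and stall >= ga_config.stall_generations:
            break
    return best, np.asarray(history)
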