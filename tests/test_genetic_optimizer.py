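import itertools

import numpy as np
import pytest

from angioseg.errors import ValidationError
from angioseg.fcm import FCMParams, run_fcm
from angioseg.genetic_optimizer import (
    BRIGHT,
    DARK,
    MID,
    GAConfig,
    SeedChromosome,
    TriClassReference,
    build_reference,
    chromosome_cost,
    crossover,
    mutate,
    run_ga,
    tier_images,
)
from angioseg.image_io import GrayImage
from angioseg.region_growing import GrowthConfig, grow_all


@pytest.fixture
def plateau_reference(three_plateau):
    res = run_fcm(three_plateau, FCMParams(n_clusters=3, rng_seed=0))
    return build_reference(three_plateau, res)


class TestBuildReference:
    def test_three_plateaus_isolated(self, three_plateau, plateau_reference):
        ref = plateau_reference
        img = three_plateau.data
        np.testing.assert_array_equal(ref.bm, np.where(img == 30, img, 0))
        np.testing.assert_array_equal(ref.gm, np.where(img == 120, img, 0))
        np.testing.assert_array_equal(ref.wm, np.where(img == 220, img, 0))
        assert ref.classify(30) == DARK
        assert ref.classify(120) == MID
        assert ref.classify(220) == BRIGHT

    def test_degenerate_constant_image(self):
        img = GrayImage(np.full((10, 10), 80.0))
        res = run_fcm(img, FCMParams(n_clusters=6, rng_seed=0))
        ref = build_reference(img, res)
        # one tier holds everything, the other reference images are zero
        supports = [int((r != 0).sum()) for r in (ref.bm, ref.gm, ref.wm)]
        assert sorted(supports) == [0, 0, 100]

    def test_rejects_small_k(self, three_plateau):
        res = run_fcm(three_plateau, FCMParams(n_clusters=2, rng_seed=0))
        with pytest.raises(ValidationError):
            build_reference(three_plateau, res)

    def test_bm_support_sort_and_scan_oracle(self, rng):
        img = GrayImage(rng.uniform(0, 255, (30, 30)))
        res = run_fcm(img, FCMParams(n_clusters=6, rng_seed=1))
        ref = build_reference(img, res)
        # oracle: pixels whose defuzzified cluster center is among the
        # lowest two centers (K=6 -> dark tier is the darkest third)
        labels = np.argmax(res.memberships, axis=0).reshape(img.shape)
        dark_clusters = np.argsort(res.centers)[:2]
        expected = np.isin(labels, dark_clusters)
        np.testing.assert_array_equal(ref.bm != 0, expected & (img.data != 0))


class TestChromosomeCost:
    def test_perfect_match_zero(self, three_plateau, plateau_reference):
        chrom = SeedChromosome(seeds=[(5, 5), (35, 5), (65, 5)])
        cfg = GrowthConfig(max_region_fraction=1.0)
        cost = chromosome_cost(chrom, three_plateau, plateau_reference, cfg)
        assert cost == pytest.approx(0.0)

    def test_near_null_segmentation(self, three_plateau, plateau_reference):
        # one seed growing only its own plateau leaves the other tiers unmatched
        chrom = SeedChromosome(seeds=[(5, 5)])
        cfg = GrowthConfig(max_region_fraction=1.0)
        cost = chromosome_cost(chrom, three_plateau, plateau_reference, cfg)
        ref = plateau_reference
        expected = (ref.gm**2 + ref.wm**2).sum() / three_plateau.data.size
        assert cost == pytest.approx(expected)

    def test_pixel_loop_oracle(self, disc_phantom):
        img, _ = disc_phantom
        res = run_fcm(img, FCMParams(n_clusters=3, rng_seed=2))
        ref = build_reference(img, res)
        chrom = SeedChromosome(seeds=[(25, 25), (3, 40)])
        cfg = GrowthConfig(criterion_mode="sd")
        cost = chromosome_cost(chrom, img, ref, cfg)
        labels, _ = grow_all(img, chrom.seeds, cfg)
        i1, i2, i3 = tier_images(img, labels, ref)
        expected = 0.0
        h, w = img.shape
        for r in range(h):
            for c in range(w):
                expected += (
                    (ref.gm[r, c] - i1[r, c]) ** 2
                    + (ref.wm[r, c] - i2[r, c]) ** 2
                    + (ref.bm[r, c] - i3[r, c]) ** 2
                )
        assert cost == pytest.approx(expected / (h * w), rel=1e-12)


class TestMutate:
    def test_rate_zero_identity(self, rng):
        cfg = GAConfig(mutation_rate=0.0)
        chrom = SeedChromosome(seeds=[(3, 4), (8, 9)])
        assert mutate(chrom, cfg, rng, (20, 20)).seeds == chrom.seeds

    def test_rate_one_fixed_length(self, rng):
        cfg = GAConfig(mutation_rate=1.0, n_min=3, n_max=3)
        chrom = SeedChromosome(seeds=[(10, 10), (11, 11), (12, 12)])
        out = mutate(chrom, cfg, rng, (30, 30))
        assert len(out.seeds) == 3
        for r, c in out.seeds:
            assert 0 <= r < 30 and 0 <= c < 30

    def test_jitter_frequency(self):
        # frequency-count oracle: a seed moves w.p. 0.2 * (1 - 1/121)
        gen = np.random.default_rng(42)
        cfg = GAConfig(mutation_rate=0.2, n_min=5, n_max=5)
        base = SeedChromosome(seeds=[(50, 50)] * 5)
        moved = trials = 0
        for _ in range(10_000):
            out = mutate(base, cfg, gen, (101, 101))
            for orig, new in zip(base.seeds, out.seeds):
                trials += 1
                moved += orig != new
        expected = 0.2 * (1 - 1 / 121)
        assert moved / trials == pytest.approx(expected, abs=0.01)

    def test_respects_bounds_many_draws(self, rng):
        cfg = GAConfig(mutation_rate=0.8, n_min=1, n_max=4)
        chrom = SeedChromosome(seeds=[(0, 0), (7, 7)])
        for _ in range(500):
            chrom = mutate(chrom, cfg, rng, (8, 8))
            chrom.validate((8, 8), cfg.n_max)
            assert 1 <= len(chrom.seeds) <= 4


class TestCrossover:
    def test_identical_parents(self, rng):
        a = SeedChromosome(seeds=[(1, 1), (2, 2), (3, 3)])
        c1, c2 = crossover(a, a.copy(), rng, GAConfig(n_max=6))
        pool = {(1, 1), (2, 2), (3, 3)}
        assert set(c1.seeds) <= pool and set(c2.seeds) <= pool

    def test_splice_oracle(self):
        cfg = GAConfig(n_min=1, n_max=10)
        a = SeedChromosome(seeds=[(0, i) for i in range(4)])
        b = SeedChromosome(seeds=[(1, i) for i in range(3)])
        gen = np.random.default_rng(7)
        c1, c2 = crossover(a, b, gen, cfg)
        # oracle: replay the same rng draws and splice by hand
        oracle = np.random.default_rng(7)
        cut_a = int(oracle.integers(5))
        cut_b = int(oracle.integers(4))
        assert c1.seeds == (a.seeds[:cut_a] + b.seeds[cut_b:])[:10]
        assert c2.seeds == (b.seeds[:cut_b] + a.seeds[cut_a:])[:10]

    def test_lengths_clipped(self, rng):
        cfg = GAConfig(n_min=2, n_max=4)
        a = SeedChromosome(seeds=[(0, i) for i in range(4)])
        b = SeedChromosome(seeds=[(1, i) for i in range(4)])
        for _ in range(200):
            c1, c2 = crossover(a, b, rng, cfg)
            assert 2 <= len(c1.seeds) <= 4
            assert 2 <= len(c2.seeds) <= 4


@pytest.fixture
def tiny_problem(disc_phantom):
    img, _ = disc_phantom
    res = run_fcm(img, FCMParams(n_clusters=3, rng_seed=0))
    return img, build_reference(img, res)


class TestRunGA:
    def test_history_monotone_non_increasing(self, tiny_problem):
        img, ref = tiny_problem
        cfg = GAConfig(population_size=8, n_generations=12, elitism=1, rng_seed=4)
        _, history = run_ga(img, ref, cfg, GrowthConfig(criterion_mode="sd"))
        assert np.all(np.diff(history) <= 0)

    def test_reproducible(self, tiny_problem):
        img, ref = tiny_problem
        cfg = GAConfig(population_size=6, n_generations=5, rng_seed=11)
        growth = GrowthConfig(criterion_mode="sd")
        best_a, hist_a = run_ga(img, ref, cfg, growth)
        best_b, hist_b = run_ga(img, ref, cfg, growth)
        assert best_a.seeds == best_b.seeds
        np.testing.assert_array_equal(hist_a, hist_b)

    def test_zero_generations_returns_initial_best(self, tiny_problem):
        img, ref = tiny_problem
        cfg = GAConfig(population_size=6, n_generations=0, rng_seed=2)
        best, history = run_ga(img, ref, cfg, GrowthConfig(criterion_mode="sd"))
        assert len(history) == 1
        assert best.fitness == history[0]

    def test_matches_exhaustive_enumeration_6x6(self):
        img = GrayImage(
            np.where(np.add.outer(np.arange(6), np.arange(6)) < 6, 40.0, 200.0)
        )
        # hand-built reference: dark tier is the 40-plateau
        ref = TriClassReference(
            gm=np.zeros((6, 6)),
            wm=np.where(img.data == 200, img.data, 0.0),
            bm=np.where(img.data == 40, img.data, 0.0),
            low_cut=100.0,
            high_cut=150.0,
        )
        growth = GrowthConfig(max_region_fraction=1.0)
        chroms = [
            SeedChromosome(seeds=[(r, c)])
            for r, c in itertools.product(range(6), range(6))
        ]
        brute = min(chromosome_cost(ch, img, ref, growth) for ch in chroms)
        cfg = GAConfig(
            population_size=20, n_generations=30, n_min=1, n_max=1, rng_seed=0
        )
        best, _ = run_ga(img, ref, cfg, growth)
        assert best.fitness == pytest.approx(brute, rel=1e-12)

    def test_beats_random_search_baseline(self, tiny_problem):
        img, ref = tiny_problem
        growth = GrowthConfig(criterion_mode="sd")
        cfg = GAConfig(population_size=10, n_generations=15, rng_seed=1)
        best, _ = run_ga(img, ref, cfg, growth)
        # random-search baseline oracle: best of 5 random chromosomes
        gen = np.random.default_rng(99)
        baselines = []
        for _ in range(5):
            seeds = [
                (int(gen.integers(50)), int(gen.integers(50)))
                for _ in range(int(gen.integers(1, 11)))
            ]
            baselines.append(chromosome_cost(SeedChromosome(seeds=seeds), img, ref, growth))
        assert best.fitness <= min(baselines)


def test_ga_config_validation():
    with pytest.raises(ValidationError):
        GAConfig(population_size=1)
    with pytest.raises(ValidationError):
        GAConfig(mutation_rate=1.5)
    with pytest.raises(ValidationError):
        GAConfig(n_min=0)
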