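"""Genetic-algorithm operators: encoding, fitness, ranking, selection,
variation, stopping, and the full evolutionary loop."""

import numpy as np
import pandas as pd
import pytest

from galoris import (
    BandFeatureMatrix,
    Chromosome,
    GaConfig,
    SearchSpace,
    SyntheticSpec,
    decode_chromosome,
    generate_band_features,
    run_galoris,
)
from galoris.bands import CHANNELS, column_names
from galoris.ga import (
    _make_split,
    evaluate_fitness,
    init_population,
    merge_significant,
    mutate,
    rank_population,
    stop_check,
    tournament_select,
    two_point_crossover,
)


def make_space(n=8, band="Alpha"):
    return SearchSpace(columns=column_names((band,))[:n])


def evaluated(genes, acc, err=None, pvals=None):
    genes = np.asarray(genes, dtype=np.int8)
    c = Chromosome(genes, ap_accuracy=acc, ap_error_rate=1 - acc if err is None else err)
    if pvals is not None:
        c.p_values = np.asarray(pvals, dtype=float)
    return c


class TestInitPopulation:
    def test_shape_no_allzero_and_determinism(self):
        space = make_space(9)
        cfg = GaConfig(population_size=100, generations=1)
        pop1 = init_population(space, cfg, np.random.default_rng(5))
        pop2 = init_population(space, cfg, np.random.default_rng(5))
        assert len(pop1) == 100
        assert all(len(c.genes) == 9 and c.genes.sum() > 0 for c in pop1)
        assert all(np.array_equal(a.genes, b.genes) for a, b in zip(pop1, pop2))

    def test_mean_bit_fraction_near_half(self):
        space = make_space(9)
        cfg = GaConfig(population_size=400, generations=1)
        pop = init_population(space, cfg, np.random.default_rng(0))
        bits = np.mean([c.genes.mean() for c in pop])
        se = 0.5 / np.sqrt(400 * 9)
        assert abs(bits - 0.5) < 3 * se + 0.01  # small upward bias from the all-zero guard

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            init_population(SearchSpace(columns=[]), GaConfig(), np.random.default_rng(0))


class TestEvaluateFitness:
    def _fit(self, X, y, genes, seed=0):
        cfg = GaConfig(seed=seed)
        split = _make_split(y, cfg.validation_fraction, np.random.default_rng(seed))
        return evaluate_fitness(Chromosome(genes), X, y, cfg, split)

    def test_perfectly_separating_feature(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 100)
        X = np.column_stack([y + 0.01 * rng.standard_normal(200), rng.standard_normal(200)])
        chrom = self._fit(X, y, [1, 0])
        assert chrom.ap_accuracy == 1.0
        assert chrom.ap_error_rate == 0.0

    def test_pure_noise_near_chance(self):
        """Noise-only features on balanced classes stay near accuracy 0.5
        on the held-out assessment portion."""
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 1000)
            X = rng.standard_normal((2000, 3))
            accs.append(self._fit(X, y, [1, 1, 1], seed=seed).ap_accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_all_zero_chromosome_floor(self):
        y = np.repeat([0, 1], 50)
        X = np.random.default_rng(0).standard_normal((100, 2))
        chrom = self._fit(X, y, [0, 0])
        assert chrom.ap_accuracy == 0.0
        assert chrom.ap_error_rate == 1.0

    def test_gene_count(self):
        assert Chromosome(np.array([1, 0, 1, 1])).ap_n_genes == 3

    def test_error_rate_complements_accuracy(self):
        rng = np.random.default_rng(3)
        y = (rng.random(400) < 0.5).astype(int)
        X = rng.standard_normal((400, 4)) + 0.8 * y[:, None]
        chrom = self._fit(X, y, [1, 1, 0, 1])
        assert chrom.ap_error_rate == pytest.approx(1.0 - chrom.ap_accuracy)


class TestRankPopulation:
    def test_priority_rules(self):
        a = evaluated([1, 0, 0], 0.9)
        b = evaluated([1, 1, 0], 0.8)
        assert rank_population([b, a])[0] is a
        # equal accuracy and error: fewer genes wins
        c = evaluated([1, 1, 1], 0.8)
        d = evaluated([0, 1, 0], 0.8)
        assert rank_population([c, d])[0] is d

    def test_matches_bruteforce_comparator(self, rng):
        pop = [
            evaluated(rng.integers(0, 2, 6), acc=rng.choice([0.7, 0.8, 0.9]),
                      err=rng.choice([0.1, 0.2]))
            for _ in range(20)
        ]
        expected = sorted(
            pop,
            key=lambda c: (-c.ap_accuracy, c.ap_error_rate, c.ap_n_genes,
                           tuple(c.genes.tolist())),
        )
        got = rank_population(pop)
        assert [tuple(c.genes) for c in got] == [tuple(c.genes) for c in expected]

    def test_unevaluated_rejected(self):
        with pytest.raises(RuntimeError):
            rank_population([Chromosome(np.array([1, 0]))])


class TestMergeSignificant:
    def test_union_of_significant_genes(self):
        a = evaluated([1, 0, 0, 0], 0.9, pvals=[0.01])
        b = evaluated([0, 1, 0, 0], 0.8, pvals=[0.02])
        merged = merge_significant([a, b], alpha=0.05)
        assert merged.genes.tolist() == [1, 1, 0, 0]

    def test_fallback_to_leader_when_nothing_significant(self):
        a = evaluated([1, 0, 1, 0], 0.9, pvals=[0.5, np.nan])
        b = evaluated([0, 1, 0, 0], 0.8, pvals=[0.9])
        merged = merge_significant([a, b], alpha=0.05)
        assert merged.genes.tolist() == a.genes.tolist()

    def test_recovers_informative_columns(self):
        """Across seeded runs on 3-informative data, the merged elite
        chromosome contains every informative column in >= 9/10 runs."""
        info = ("Delta_AF3", "Alpha_F3", "Beta_O2")
        cols = column_names(("Delta", "Alpha", "Beta", "Gamma"))
        space = SearchSpace(columns=cols)
        hits = 0
        for seed in range(10):
            spec = SyntheticSpec(
                n_samples=1000, bands=("Delta", "Alpha", "Beta", "Gamma"),
                effect_size=2.0, informative_columns=info, seed=300 + seed,
            )
            matrix, labels, _ = generate_band_features(spec)
            X = matrix.values[cols].to_numpy()
            cfg = GaConfig(population_size=20, generations=1, seed=seed)
            rng = np.random.default_rng(seed)
            split = _make_split(labels, cfg.validation_fraction, rng)
            pop = [
                evaluate_fitness(c, X, labels, cfg, split)
                for c in init_population(space, cfg, rng)
            ]
            merged = merge_significant(rank_population(pop)[:10], cfg.alpha)
            selected = set(decode_chromosome(merged.genes, space))
            hits += set(info) <= selected
        assert hits >= 9


class TestTournamentSelect:
    def test_full_tournament_returns_global_best(self, rng):
        pop = rank_population([evaluated(rng.integers(0, 2, 4), acc=a)
                               for a in (0.6, 0.7, 0.9, 0.8)])
        winner = tournament_select(pop, t=4, rng=rng)
        assert winner is pop[0]

    def test_selection_pressure_grows_with_t(self):
        pop = rank_population(
            [evaluated(np.eye(16, dtype=int)[i], acc=0.5 + 0.03 * i) for i in range(16)]
        )
        mean_ranks = []
        for t in (1, 2, 5):
            rng = np.random.default_rng(7)
            ranks = [pop.index(tournament_select(pop, t, rng)) for _ in range(1000)]
            mean_ranks.append(np.mean(ranks))
        assert mean_ranks[0] > mean_ranks[1] > mean_ranks[2]

    def test_oversized_tournament_rejected(self, rng):
        pop = [evaluated([1, 0], 0.5)]
        with pytest.raises(ValueError):
            tournament_select(pop, t=2, rng=rng)


class TestTwoPointCrossover:
    def test_identical_central_region_children_equal_parents(self, rng):
        """When the parents agree on the exchanged central segment the
        children reproduce the parents."""
        p1 = Chromosome(np.array([0, 0, 1, 0, 1, 0, 1]))
        p2 = Chromosome(np.array([1, 0, 1, 0, 1, 0, 1]))  # differ only at position 0
        for _ in range(20):
            c1, c2 = two_point_crossover(p1, p2, pc=1.0, rng=rng)
            pair = {tuple(c1.genes), tuple(c2.genes)}
            assert pair == {tuple(p1.genes), tuple(p2.genes)}

    def test_identical_parents_identical_children(self, rng):
        p = Chromosome(np.array([1, 0, 1, 1, 0]))
        c1, c2 = two_point_crossover(p, p, pc=1.0, rng=rng)
        assert np.array_equal(c1.genes, p.genes)
        assert np.array_equal(c2.genes, p.genes)

    def test_positionwise_allele_conservation(self, rng):
        for _ in range(100):
            g1 = rng.integers(0, 2, 12)
            g2 = rng.integers(0, 2, 12)
            c1, c2 = two_point_crossover(Chromosome(g1), Chromosome(g2), pc=1.0, rng=rng)
            assert np.array_equal(c1.genes + c2.genes, g1 + g2)

    def test_no_crossover_below_probability(self, rng):
        p1, p2 = Chromosome(np.array([1, 1, 0, 0])), Chromosome(np.array([0, 0, 1, 1]))
        c1, c2 = two_point_crossover(p1, p2, pc=0.0, rng=rng)
        assert np.array_equal(c1.genes, p1.genes)
        assert np.array_equal(c2.genes, p2.genes)

    def test_short_chromosomes_copied(self, rng):
        p1, p2 = Chromosome(np.array([1, 0])), Chromosome(np.array([0, 1]))
        c1, c2 = two_point_crossover(p1, p2, pc=1.0, rng=rng)
        assert np.array_equal(c1.genes, p1.genes)


class TestMutate:
    def test_pm_zero_unchanged(self, rng):
        genes = np.array([1, 0, 1, 0, 1])
        assert np.array_equal(mutate(Chromosome(genes), 0.0, rng).genes, genes)

    def test_pm_one_complements(self, rng):
        genes = np.array([1, 0, 1, 0])
        assert np.array_equal(mutate(Chromosome(genes), 1.0, rng).genes, 1 - genes)

    def test_allzero_guard(self, rng):
        out = mutate(Chromosome(np.array([1, 1, 1])), 1.0, rng)
        assert out.genes.sum() == 1

    def test_expected_flip_count(self):
        rng = np.random.default_rng(17)
        genes = np.zeros(20, dtype=np.int8)
        genes[:10] = 1  # keep away from the all-zero guard
        pm, trials = 0.1, 1000
        flips = [
            int(np.sum(mutate(Chromosome(genes), pm, rng).genes != genes))
            for _ in range(trials)
        ]
        expected = pm * len(genes)
        se = np.sqrt(len(genes) * pm * (1 - pm) / trials)
        assert abs(np.mean(flips) - expected) < 3 * se


class TestStopCheck:
    def test_generation_budget(self):
        best = evaluated([1, 0], 0.9)
        cfg = GaConfig(generations=30)
        assert stop_check(30, best, cfg)
        assert not stop_check(5, best, cfg)

    def test_perfect_fitness_stops_early(self):
        best = evaluated([1, 0], 1.0, err=0.0)
        assert stop_check(2, best, GaConfig(generations=30))


class TestDecodeChromosome:
    def test_single_band_space(self):
        space = SearchSpace(columns=[f"Alpha_{ch}" for ch in CHANNELS])
        genes = [0, 0, 1, 0, 1, 0, 1, 0, 0]
        assert decode_chromosome(np.array(genes), space) == [
            "Alpha_F3", "Alpha_F8", "Alpha_O2",
        ]

    def test_all_zero_empty(self):
        space = make_space(4)
        assert decode_chromosome(np.zeros(4, dtype=int), space) == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decode_chromosome(np.array([1, 0]), make_space(4))


@pytest.fixture(scope="module")
def run_inputs():
    info = ("Delta_AF3", "Alpha_F3", "Beta_O2")
    spec = SyntheticSpec(
        n_samples=600, bands=("Delta", "Alpha", "Beta"), effect_size=2.0,
        informative_columns=info, seed=31,
    )
    matrix, labels, _ = generate_band_features(spec)
    space = SearchSpace(columns=matrix.column_names)
    cfg = GaConfig(generations=5, population_size=20, elite_size=5, seed=13)
    return matrix, labels, space, cfg


class TestRunGaloris:
    def test_deterministic_under_fixed_seed(self, run_inputs):
        matrix, labels, space, cfg = run_inputs
        best1, _, hist1 = run_galoris(matrix, labels, space, cfg)
        best2, _, hist2 = run_galoris(matrix, labels, space, cfg)
        assert np.array_equal(best1.genes, best2.genes)
        pd.testing.assert_frame_equal(hist1, hist2)

    def test_elitism_best_accuracy_non_decreasing(self, run_inputs):
        matrix, labels, space, cfg = run_inputs
        _, _, hist = run_galoris(matrix, labels, space, cfg)
        assert (hist["best_accuracy"].diff().dropna() >= 0).all()

    def test_single_column_space(self, small_dataset):
        matrix, labels, _, _ = small_dataset
        space = SearchSpace(columns=["Alpha_F3"])
        cfg = GaConfig(generations=2, population_size=4, tournament_size=2, seed=1)
        best, structured, hist = run_galoris(matrix, labels, space, cfg)
        assert best.genes.tolist() == [1]
        assert structured.column_names == ["Alpha_F3"]
        assert hist["generation"].iloc[-1] <= 2

    def test_structured_dataset_follows_space_order(self, run_inputs):
        matrix, labels, space, cfg = run_inputs
        best, structured, _ = run_galoris(matrix, labels, space, cfg)
        expected = [c for c, g in zip(space.columns, best.genes) if g]
        assert structured.column_names == expected
        assert structured.n_samples == matrix.n_samples
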