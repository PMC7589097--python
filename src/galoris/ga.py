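"""Genetic-algorithm feature selection with a logistic-regression fitness.

A candidate feature subset is a binary chromosome over the search-space
columns.  Each chromosome's fitness is summarized by four adaptation
parameters computed from a logistic-regression fit on its selected
columns:

* fit accuracy — correct / (correct + incorrect) on a held-out assessment
  portion of the samples, at probability cut 0.5;
* error rate — the misclassified fraction (1 - accuracy);
* gene count — the number of selected columns;
* per-gene significance — two-sided Wald p-values of the fitted
  coefficients, flagged at level alpha.

Chromosomes are ranked by descending accuracy, then ascending error rate,
then ascending gene count (fewer features win a tie), with the gene vector
itself as a final deterministic tie-break.  Evolution combines tournament
selection under that ranking, two-point crossover, independent bit-flip
mutation, and an elitist carry-over: the union of all significant genes
across the current elite is injected unchanged into the next generation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .features import BandFeatureMatrix
from .screening import SearchSpace

__all__ = [
    "Chromosome",
    "GaConfig",
    "StructuredDataset",
    "init_population",
    "evaluate_fitness",
    "rank_population",
    "merge_significant",
    "tournament_select",
    "two_point_crossover",
    "mutate",
    "stop_check",
    "decode_chromosome",
    "run_galoris",
    "exhaustive_best",
]

logger = logging.getLogger(__name__)


@dataclass
class GaConfig:
    """Run parameters; the defaults are the study configuration
    (30 generations, population 100, tournament size 5, crossover 0.8,
    mutation 0.1, significance 0.05)."""

    generations: int = 30
    population_size: int = 100
    tournament_size: int = 5
    crossover_probability: float = 0.8
    mutation_probability: float = 0.1
    alpha: float = 0.05
    validation_fraction: float = 0.2
    elite_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossover_probability <= 1.0:
            raise ValueError("crossover_probability must lie in [0, 1]")
        if not 0.0 <= self.mutation_probability <= 1.0:
            raise ValueError("mutation_probability must lie in [0, 1]")
        if self.tournament_size > self.population_size:
            raise ValueError("tournament_size cannot exceed population_size")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie strictly in (0, 1)")
        if self.generations < 1 or self.population_size < 2:
            raise ValueError("need generations >= 1 and population_size >= 2")


@dataclass(eq=False)
class Chromosome:
    """Binary gene vector plus its adaptation parameters after evaluation.

    ``coefficients`` and ``p_values`` are aligned with the *selected* gene
    indices (``selected_indices``); genes that are 0 carry no coefficient.
    """

    genes: np.ndarray
    ap_accuracy: float | None = None
    ap_error_rate: float | None = None
    intercept: float | None = None
    coefficients: np.ndarray | None = None
    p_values: np.ndarray | None = None
    ridge_fallback: bool = False

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=np.int8)
        if not np.isin(self.genes, (0, 1)).all():
            raise ValueError("genes must be a binary vector")

    @property
    def ap_n_genes(self) -> int:
        return int(self.genes.sum())

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.genes)

    @property
    def evaluated(self) -> bool:
        return self.ap_accuracy is not None

    def significant_indices(self, alpha: float) -> np.ndarray:
        """Gene indices whose Wald p-value is <= alpha."""
        if self.p_values is None:
            return np.array([], dtype=int)
        with np.errstate(invalid="ignore"):
            keep = self.p_values <= alpha
        keep &= np.isfinite(self.p_values)
        return self.selected_indices[keep]

    def rank_key(self) -> tuple:
        if not self.evaluated:
            raise RuntimeError("chromosome has not been evaluated")
        return (
            -self.ap_accuracy,
            self.ap_error_rate,
            self.ap_n_genes,
            tuple(self.genes.tolist()),
        )


@dataclass
class StructuredDataset:
    """The restructured dataset: selected feature columns + labels."""

    features: pd.DataFrame
    labels: np.ndarray
    source_chromosome: Chromosome

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def column_names(self) -> list[str]:
        return list(self.features.columns)


def init_population(space: SearchSpace, config: GaConfig, rng: np.random.Generator) -> list[Chromosome]:
    """Random initial population: genes i.i.d. Bernoulli(0.5), all-zero
    vectors resampled."""
    p = len(space)
    if p == 0:
        raise ValueError("search space is empty; nothing to select from")
    population = []
    for _ in range(config.population_size):
        genes = rng.integers(0, 2, size=p, dtype=np.int8)
        while genes.sum() == 0:
            genes = rng.integers(0, 2, size=p, dtype=np.int8)
        population.append(Chromosome(genes))
    return population


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood logistic fit; returns (params, p_values, ridge_flag).

    params[0] is the intercept.  Under (quasi-)separation or a failed
    Newton iteration the fit falls back to an L2-stabilized estimate whose
    Wald p-values are not trustworthy and are reported as NaN.
    """
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100, warn_convergence=False)
        params, pvals = np.asarray(res.params), np.asarray(res.pvalues)
        if np.isfinite(params).all() and np.isfinite(res.bse).all() and res.mle_retvals.get("converged", True):
            return params, pvals, False
    except Exception:  # PerfectSeparation / LinAlgError / overflow
        pass
    ridge = LogisticRegression(C=1.0, max_iter=1000)
    ridge.fit(X, y)
    params = np.concatenate([ridge.intercept_, ridge.coef_.ravel()])
    pvals = np.full(params.shape, np.nan)
    return params, pvals, True


def evaluate_fitness(
    chrom: Chromosome,
    data: np.ndarray,
    labels: np.ndarray,
    config: GaConfig,
    split: tuple[np.ndarray, np.ndarray],
) -> Chromosome:
    """Fit the logistic model on the build portion, score on the assess
    portion, and fill in the adaptation parameters.

    ``split`` is the (build_idx, assess_idx) sample split shared by every
    chromosome in a run so that fitnesses are directly comparable.  An
    all-zero chromosome gets the fitness floor (accuracy 0, error 1).
    """
    if chrom.ap_n_genes == 0:
        return replace(chrom, ap_accuracy=0.0, ap_error_rate=1.0)
    build_idx, assess_idx = split
    sel = chrom.selected_indices
    X_build, y_build = data[np.ix_(build_idx, sel)], labels[build_idx]
    X_assess, y_assess = data[np.ix_(assess_idx, sel)], labels[assess_idx]
    if np.unique(y_build).size < 2:
        raise ValueError("fitting portion must contain both classes")

    params, pvals, ridge_flag = _fit_logistic(X_build, y_build)
    if ridge_flag:
        logger.debug("ridge-stabilized fit for chromosome with %d genes", len(sel))
    eta = params[0] + X_assess @ params[1:]
    pred = (1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500))) >= 0.5).astype(int)
    accuracy = float(np.mean(pred == y_assess))
    return replace(
        chrom,
        ap_accuracy=accuracy,
        ap_error_rate=1.0 - accuracy,
        intercept=float(params[0]),
        coefficients=params[1:],
        p_values=pvals[1:],
        ridge_fallback=ridge_flag,
    )


def rank_population(population: list[Chromosome]) -> list[Chromosome]:
    """Priority order: accuracy desc, error rate asc, gene count asc,
    lexicographic genes."""
    return sorted(population, key=Chromosome.rank_key)


def merge_significant(elite: list[Chromosome], alpha: float) -> Chromosome:
    """Union of all significant genes across the elite, as one chromosome.

    Falls back to the top-ranked elite member when no gene anywhere in the
    elite is significant.
    """
    if not elite:
        raise ValueError("elite list is empty")
    length = len(elite[0].genes)
    union = np.zeros(length, dtype=np.int8)
    for chrom in elite:
        union[chrom.significant_indices(alpha)] = 1
    if union.sum() == 0:
        logger.debug("no significant genes in the elite; carrying the leader forward")
        return Chromosome(elite[0].genes.copy())
    return Chromosome(union)


def tournament_select(
    ranked: list[Chromosome], t: int, rng: np.random.Generator
) -> Chromosome:
    """Draw t chromosomes uniformly without replacement; return the best."""
    if t > len(ranked):
        raise ValueError(f"tournament size {t} exceeds population {len(ranked)}")
    picks = rng.choice(len(ranked), size=t, replace=False)
    return ranked[min(picks)]  # list is already in rank order


def two_point_crossover(
    parent1: Chromosome,
    parent2: Chromosome,
    pc: float,
    rng: np.random.Generator,
) -> tuple[Chromosome, Chromosome]:
    """With probability pc, swap the central segment between two cut points.

    Child 1 keeps parent 1's lateral segments around parent 2's central
    segment; child 2 is the complement.  Chromosomes shorter than 3 genes
    cannot be cut twice and are copied through.
    """
    g1, g2 = parent1.genes, parent2.genes
    if len(g1) != len(g2):
        raise ValueError("parents must have equal gene lengths")
    if len(g1) < 3:
        logger.debug("chromosome too short for two-point crossover; copying parents")
        return Chromosome(g1.copy()), Chromosome(g2.copy())
    if rng.random() >= pc:
        return Chromosome(g1.copy()), Chromosome(g2.copy())
    i, j = np.sort(rng.choice(np.arange(1, len(g1)), size=2, replace=False))
    c1 = np.concatenate([g1[:i], g2[i:j], g1[j:]])
    c2 = np.concatenate([g2[:i], g1[i:j], g2[j:]])
    return Chromosome(c1), Chromosome(c2)


def mutate(chrom: Chromosome, pm: float, rng: np.random.Generator) -> Chromosome:
    """Flip each gene independently with probability pm; an all-zero result
    gets one random gene set back on."""
    flips = rng.random(len(chrom.genes)) < pm
    genes = np.where(flips, 1 - chrom.genes, chrom.genes).astype(np.int8)
    if genes.sum() == 0:
        genes[rng.integers(len(genes))] = 1
    return Chromosome(genes)


def stop_check(generation: int, best: Chromosome, config: GaConfig) -> bool:
    """Stop when the generation budget is spent or the fitness criteria
    are perfect (accuracy 1, error rate 0)."""
    if not best.evaluated:
        raise RuntimeError("best chromosome has not been evaluated")
    if generation >= config.generations:
        return True
    return best.ap_accuracy == 1.0 and best.ap_error_rate == 0.0


def decode_chromosome(genes: np.ndarray, space: SearchSpace) -> list[str]:
    """Names of the selected columns, in search-space order."""
    genes = np.asarray(genes, dtype=np.int8)
    if len(genes) != len(space):
        raise ValueError(
            f"gene vector length {len(genes)} does not match the "
            f"{len(space)}-column search space"
        )
    return [name for name, g in zip(space.columns, genes) if g == 1]


def _make_split(
    labels: np.ndarray, validation_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One stratified build/assess sample split shared by the whole run."""
    idx = np.arange(len(labels))
    build, assess = train_test_split(
        idx,
        test_size=validation_fraction,
        stratify=labels,
        random_state=int(rng.integers(2**31 - 1)),
    )
    return np.sort(build), np.sort(assess)


def run_galoris(
    data: BandFeatureMatrix | pd.DataFrame,
    labels: np.ndarray,
    space: SearchSpace,
    config: GaConfig | None = None,
) -> tuple[Chromosome, StructuredDataset, pd.DataFrame]:
    """Full evolutionary loop; returns (best chromosome, structured
    dataset, per-generation history).

    Each generation: evaluate -> rank -> merge the elite's significant
    genes (elitist carry-over) -> tournament-selected parents -> two-point
    crossover -> mutation.  The best-ever chromosome is tracked across
    generations, so the history's best accuracy is non-decreasing.  The
    whole run is deterministic given ``config.seed``.
    """
    if config is None:
        config = GaConfig()
    frame = data.values if isinstance(data, BandFeatureMatrix) else pd.DataFrame(data)
    missing = [c for c in space.columns if c not in frame.columns]
    if missing:
        raise ValueError(f"search-space columns missing from data: {missing}")
    X = frame[space.columns].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size != 2:
        raise ValueError("labels must contain exactly two classes")

    rng = np.random.default_rng(config.seed)
    split = _make_split(y, config.validation_fraction, rng)
    cache: dict[bytes, Chromosome] = {}

    def evaluate(chrom: Chromosome) -> Chromosome:
        key = chrom.genes.tobytes()
        hit = cache.get(key)
        if hit is None:
            hit = evaluate_fitness(chrom, X, y, config, split)
            cache[key] = hit
        return hit

    population = [evaluate(c) for c in init_population(space, config, rng)]
    best_ever: Chromosome | None = None
    history_rows = []
    generation = 0
    while True:
        ranked = rank_population(population)
        if best_ever is None or ranked[0].rank_key() < best_ever.rank_key():
            best_ever = ranked[0]
        history_rows.append(
            {
                "generation": generation,
                "best_accuracy": best_ever.ap_accuracy,
                "best_error_rate": best_ever.ap_error_rate,
                "best_n_genes": best_ever.ap_n_genes,
                "generation_best_accuracy": ranked[0].ap_accuracy,
                "mean_accuracy": float(np.mean([c.ap_accuracy for c in ranked])),
            }
        )
        if stop_check(generation, best_ever, config):
            break
        generation += 1

        elite = ranked[: config.elite_size]
        next_population = [evaluate(merge_significant(elite, config.alpha))]
        while len(next_population) < config.population_size:
            p1 = tournament_select(ranked, config.tournament_size, rng)
            p2 = tournament_select(ranked, config.tournament_size, rng)
            c1, c2 = two_point_crossover(p1, p2, config.crossover_probability, rng)
            for child in (c1, c2):
                if len(next_population) < config.population_size:
                    next_population.append(
                        evaluate(mutate(child, config.mutation_probability, rng))
                    )
        population = next_population

    structured = StructuredDataset(
        features=frame[decode_chromosome(best_ever.genes, space)].copy(),
        labels=y,
        source_chromosome=best_ever,
    )
    return best_ever, structured, pd.DataFrame(history_rows)


def exhaustive_best(
    data: BandFeatureMatrix | pd.DataFrame,
    labels: np.ndarray,
    space: SearchSpace,
    config: GaConfig | None = None,
) -> Chromosome:
    """Brute-force enumeration of every non-empty subset, under the same
    fitness and ranking as the GA.  Only feasible for small spaces; used
    as an independent optimum for benchmarking the heuristic search."""
    if config is None:
        config = GaConfig()
    p = len(space)
    if p > 16:
        raise ValueError(f"exhaustive search over {p} columns is not feasible")
    frame = data.values if isinstance(data, BandFeatureMatrix) else pd.DataFrame(data)
    X = frame[space.columns].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(config.seed)
    split = _make_split(y, config.validation_fraction, rng)

    best: Chromosome | None = None
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            genes = np.zeros(p, dtype=np.int8)
            genes[list(subset)] = 1
            cand = evaluate_fitness(Chromosome(genes), X, y, config, split)
            if best is None or cand.rank_key() < best.rank_key():
                best = cand
    return best
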