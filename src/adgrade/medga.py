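"""Evolutionary search over CNN hyperparameters (the "medical GA").

A genome is one hyperparameter tuple (learning rate, conv-layer count,
per-layer filter list, dropout rate). The algorithm evolves a population by
fitness-proportional (roulette-wheel) selection, uniform gene-wise
crossover with a last-filter reuse rule for length mismatches, gene-wise
mutation by domain resampling, and single-individual elitism, so the best
fitness seen is non-decreasing across generations.

Fitness is either plain validation accuracy of the trained candidate CNN,
or a multi-objective blend 0.7 * accuracy + 0.3 * (1 - normalized parameter
count), where the parameter count is min-max normalized over the counts
achievable inside the search domain.

Class weights for imbalance-aware training follow w_c = N_total / (N_c * K);
they satisfy sum_c w_c * N_c = N_total identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_LR_SET = (1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2)
DEFAULT_LAYER_SET = (2, 3, 4, 5)
DEFAULT_FILTER_SET = (16, 32, 64, 128, 256)
DEFAULT_DROPOUT_INTERVAL = (0.1, 0.6)


class InvalidConfigError(ValueError):
    pass


class DegenerateClassError(ValueError):
    pass


class InvalidFitnessError(ValueError):
    pass


class EvaluatorContractError(ValueError):
    pass


@dataclass(frozen=True)
class Genome:
    """One candidate: (lr, n_layers, filters, dropout)."""

    lr: float
    n_layers: int
    filters: tuple[int, ...]
    dropout: float

    def __post_init__(self):
        if len(self.filters) != self.n_layers:
            raise InvalidConfigError(
                f"filters length {len(self.filters)} != n_layers {self.n_layers}"
            )


@dataclass(frozen=True)
class Domains:
    """Allowed values per gene; every operator stays closed over these."""

    lr_set: tuple[float, ...] = DEFAULT_LR_SET
    layer_set: tuple[int, ...] = DEFAULT_LAYER_SET
    filter_set: tuple[int, ...] = DEFAULT_FILTER_SET
    dropout_interval: tuple[float, float] = DEFAULT_DROPOUT_INTERVAL

    def __post_init__(self):
        if not (self.lr_set and self.layer_set and self.filter_set):
            raise InvalidConfigError("domain sets must be nonempty")
        lo, hi = self.dropout_interval
        if not (0.0 <= lo <= hi <= 1.0):
            raise InvalidConfigError("dropout interval must lie within [0, 1]")

    def contains(self, g: Genome) -> bool:
        lo, hi = self.dropout_interval
        return (
            g.lr in self.lr_set
            and g.n_layers in self.layer_set
            and all(f in self.filter_set for f in g.filters)
            and lo <= g.dropout <= hi
        )

    def sample(self, rng: np.random.Generator) -> Genome:
        nl = int(rng.choice(self.layer_set))
        return Genome(
            lr=float(rng.choice(self.lr_set)),
            n_layers=nl,
            filters=tuple(int(rng.choice(self.filter_set)) for _ in range(nl)),
            dropout=float(rng.uniform(*self.dropout_interval)),
        )


@dataclass
class Population:
    generation: int
    genomes: list[Genome]
    fitnesses: np.ndarray | None = None


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 10
    p_mut: float = 0.5
    crossover_rate: float = 0.70
    elitism_count: int = 1
    fitness_mode: str = "accuracy"  # or "multi_objective"
    accuracy_weight: float = 0.7
    param_weight: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_mut, self.crossover_rate):
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError("probabilities must lie in [0, 1]")
        if self.fitness_mode not in ("accuracy", "multi_objective"):
            raise InvalidConfigError(f"unknown fitness_mode {self.fitness_mode!r}")
        if self.fitness_mode == "multi_objective" and not np.isclose(
            self.accuracy_weight + self.param_weight, 1.0
        ):
            raise InvalidConfigError("accuracy_weight + param_weight must equal 1")


@dataclass(frozen=True)
class ClassWeights:
    weights: tuple[float, ...]
    counts: tuple[int, ...]
    n_total: int
    k: int

    def per_sample(self, labels: np.ndarray) -> np.ndarray:
        return np.asarray(self.weights)[labels]


def class_weights(counts) -> ClassWeights:
    """w_c = N_total / (N_c * K); identity sum_c w_c N_c = N_total holds."""
    counts = tuple(int(c) for c in counts)
    if any(c <= 0 for c in counts):
        raise DegenerateClassError(f"all class counts must be > 0, got {counts}")
    n_total = sum(counts)
    k = len(counts)
    return ClassWeights(
        weights=tuple(n_total / (c * k) for c in counts),
        counts=counts,
        n_total=n_total,
        k=k,
    )


def init_population(domains: Domains, n: int, seed: int) -> Population:
    """N genomes sampled uniformly and independently from the domains."""
    if n < 2:
        raise InvalidConfigError(f"population size must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    return Population(generation=0, genomes=[domains.sample(rng) for _ in range(n)])


def _param_extremes(domains: Domains, param_counter) -> tuple[int, int]:
    """Exact min/max of param_counter over every (n_layers, filters) combo."""
    import itertools

    counts = []
    for nl in domains.layer_set:
        for filters in itertools.product(domains.filter_set, repeat=nl):
            counts.append(param_counter(nl, filters))
    return min(counts), max(counts)


def fitness(genome: Genome, evaluator, config: GAConfig, domains: Domains | None = None) -> float:
    """Eq.-style fitness: plain accuracy, or the 0.7/0.3 accuracy-vs-size blend."""
    accuracy, params = evaluator(genome)
    if not 0.0 <= accuracy <= 1.0:
        raise EvaluatorContractError(f"accuracy {accuracy} outside [0, 1]")
    if config.fitness_mode == "accuracy":
        return float(accuracy)
    if domains is None:
        raise InvalidConfigError("multi_objective fitness needs the search domains")
    pmin, pmax = getattr(evaluator, "param_extremes", (None, None))
    if pmin is None:
        counter = getattr(evaluator, "param_counter")
        pmin, pmax = _param_extremes(domains, counter)
        evaluator.param_extremes = (pmin, pmax)
    norm = 0.0 if pmax == pmin else (params - pmin) / (pmax - pmin)
    return float(config.accuracy_weight * accuracy + config.param_weight * (1.0 - norm))


def selection_probs(fitnesses: np.ndarray) -> np.ndarray:
    """Roulette-wheel probabilities: f_i / sum f, or uniform when the sum is 0."""
    f = np.asarray(fitnesses, dtype=np.float64)
    if not np.isfinite(f).all() or (f < 0).any():
        raise InvalidFitnessError("fitnesses must be finite and >= 0")
    total = f.sum()
    if total == 0.0:
        return np.full(len(f), 1.0 / len(f))
    return f / total


def _roulette_pick(probs: np.ndarray, rng: np.random.Generator) -> int:
    # single uniform draw against the cumulative distribution
    return int(np.searchsorted(np.cumsum(probs), rng.random(), side="right").clip(0, len(probs) - 1))


def crossover(parent_a: Genome, parent_b: Genome, seed) -> Genome:
    """Uniform gene-wise crossover; shorter parents reuse their last filter."""
    rng = seed if hasattr(seed, "random") else np.random.default_rng(seed)
    lr = parent_a.lr if rng.random() < 0.5 else parent_b.lr
    nl = parent_a.n_layers if rng.random() < 0.5 else parent_b.n_layers
    dropout = parent_a.dropout if rng.random() < 0.5 else parent_b.dropout
    filters = []
    for j in range(nl):
        src = parent_a.filters if rng.random() < 0.5 else parent_b.filters
        filters.append(src[j] if j < len(src) else src[-1])
    return Genome(lr=lr, n_layers=nl, filters=tuple(filters), dropout=dropout)


def mutate(genome: Genome, domains: Domains, p_mut: float, seed) -> Genome:
    """Resample each gene with probability p_mut; a layer-count mutation
    regenerates the whole filter list at the new length."""
    if not 0.0 <= p_mut <= 1.0:
        raise InvalidConfigError(f"p_mut must lie in [0, 1], got {p_mut}")
    rng = seed if hasattr(seed, "random") else np.random.default_rng(seed)
    lr = float(rng.choice(domains.lr_set)) if rng.random() < p_mut else genome.lr
    if rng.random() < p_mut:
        nl = int(rng.choice(domains.layer_set))
        filters = tuple(int(rng.choice(domains.filter_set)) for _ in range(nl))
    else:
        nl = genome.n_layers
        filters = tuple(
            int(rng.choice(domains.filter_set)) if rng.random() < p_mut else f
            for f in genome.filters
        )
    dropout = (
        float(rng.uniform(*domains.dropout_interval))
        if rng.random() < p_mut
        else genome.dropout
    )
    return Genome(lr=lr, n_layers=nl, filters=filters, dropout=dropout)


def evolve(
    domains: Domains, evaluator, config: GAConfig
) -> tuple[Genome, list[dict]]:
    """Run the full GA; returns (best-ever genome, per-generation history).

    Per generation: evaluate -> copy the elite -> roulette parent selection
    -> crossover with probability ``crossover_rate`` (else clone the fitter
    parent) -> mutation. Fitness evaluations are cached per genome.
    """
    rng = np.random.default_rng(config.seed)
    pop = init_population(domains, config.population_size, seed=int(rng.integers(2**31)))
    cache: dict[Genome, float] = {}
    history: list[dict] = []
    best_genome, best_fit = None, -np.inf

    def evaluate(g: Genome) -> float:
        if g not in cache:
            cache[g] = fitness(g, evaluator, config, domains)
        return cache[g]

    for t in range(config.generations):
        fits = np.array([evaluate(g) for g in pop.genomes])
        pop.fitnesses = fits
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_genome = pop.genomes[gen_best]
        history.append(
            {
                "generation": t,
                "best_fitness": float(fits[gen_best]),
                "mean_fitness": float(fits.mean()),
                "best_so_far": best_fit,
                "best_genome": pop.genomes[gen_best],
            }
        )
        if t == config.generations - 1:
            break
        probs = selection_probs(fits)
        children = [pop.genomes[gen_best]] * config.elitism_count
        while len(children) < config.population_size:
            ia, ib = _roulette_pick(probs, rng), _roulette_pick(probs, rng)
            pa, pb = pop.genomes[ia], pop.genomes[ib]
            if rng.random() < config.crossover_rate:
                child = crossover(pa, pb, rng)
            else:
                child = pa if fits[ia] >= fits[ib] else pb
            children.append(mutate(child, domains, config.p_mut, rng))
        pop = Population(generation=t + 1, genomes=children)
    return best_genome, history


def surrogate_evaluator(target: Genome, param_counter=None):
    """Deterministic test double: similarity-to-target plays "accuracy".

    Similarity is the mean of four gene matches: exact learning-rate match,
    exact layer-count match, positionwise filter match fraction, and a
    dropout match counted when within ±0.05 of the target. Symmetric in
    (target, query).
    """

    def gene_similarity(g: Genome) -> float:
        s_lr = 1.0 if g.lr == target.lr else 0.0
        s_nl = 1.0 if g.n_layers == target.n_layers else 0.0
        m = max(len(g.filters), len(target.filters))
        matches = sum(
            1
            for j in range(m)
            if j < len(g.filters)
            and j < len(target.filters)
            and g.filters[j] == target.filters[j]
        )
        s_filt = matches / m
        s_drop = 1.0 if abs(g.dropout - target.dropout) <= 0.05 else 0.0
        return (s_lr + s_nl + s_filt + s_drop) / 4.0

    def evaluator(g: Genome) -> tuple[float, int]:
        params = param_counter(g.n_layers, g.filters) if param_counter else 1
        return gene_similarity(g), params

    if param_counter is not None:
        evaluator.param_counter = param_counter
    return evaluator


__all__ = [
    "DEFAULT_LR_SET",
    "DEFAULT_LAYER_SET",
    "DEFAULT_FILTER_SET",
    "DEFAULT_DROPOUT_INTERVAL",
    "Genome",
    "Domains",
    "Population",
    "GAConfig",
    "ClassWeights",
    "InvalidConfigError",
    "DegenerateClassError",
    "InvalidFitnessError",
    "EvaluatorContractError",
    "class_weights",
    "init_population",
    "fitness",
    "selection_probs",
    "crossover",
    "mutate",
    "evolve",
    "surrogate_evaluator",
]
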