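"""Customized genetic algorithm for evolving candidate networks.

The GA operates per target gene.  Structure and weights evolve together:
tournament selection fills a mating pool; individuals with the same neuron
count are paired and may swap one whole neuron (crossover); mutation
adjusts input counts, rewires connections and perturbs weights; elitism
copies the best individuals unchanged, making best fitness monotone.

The neuron count of an individual never changes after initialization (no
operator alters it); diversity in chain depth comes from stratified
initialization over c in {0..C}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fitness import FitnessReport, evaluate_fitness
from .model import CandidateNetwork, NeuronSpec, validate

__all__ = [
    "GAConfig",
    "EvolutionTrace",
    "GenerationRecord",
    "init_population",
    "tournament_select",
    "pair_for_crossover",
    "crossover",
    "mutate",
    "evolve",
]


@dataclass
class GAConfig:
    """Evolutionary hyperparameters (all overridable).

    Defaults are conventional mid-size GA settings: moderate population,
    high crossover and low per-site mutation probability, light elitism,
    and symmetric weight bounds wide enough for the sigmoid to saturate.
    """

    population_size: int = 100
    max_generations: int = 200
    p_crossover: float = 0.7
    p_mutation: float = 0.1
    tournament_size: int = 3
    elite_count: int = 2
    w_min: float = -5.0
    w_max: float = 5.0
    mutation_sd: float = 0.5
    stagnation_limit: int = 50
    mu_init_prob: float = 0.5

    def validate(self) -> None:
        if not (0.0 <= self.p_crossover <= 1.0 and 0.0 <= self.p_mutation <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if not (self.w_min < 0.0 < self.w_max):
            raise ValueError("weight bounds must satisfy w_min < 0 < w_max")
        if self.elite_count >= self.population_size:
            raise ValueError("elite_count must be smaller than population_size")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")


@dataclass
class GenerationRecord:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_k: int
    best_c: int


@dataclass
class EvolutionTrace:
    """Per-generation summary of one GA run."""

    records: list[GenerationRecord] = field(default_factory=list)
    best_per_generation: list[CandidateNetwork] = field(default_factory=list)
    termination: str = ""

    def to_rows(self) -> list[dict]:
        return [
            {
                "generation": r.generation,
                "best_fitness": r.best_fitness,
                "mean_fitness": r.mean_fitness,
                "best_k": r.best_k,
                "best_c": r.best_c,
            }
            for r in self.records
        ]


# ---------------------------------------------------------------------------
# initialization

def _allowed_inputs(net: CandidateNetwork, position: int) -> list[int]:
    """Node ids neuron ``position`` (1-based) may take as inputs."""
    genes = [net.C + g for g in range(1, net.P + 1) if g != net.target_gene]
    if position == net.n_neurons:  # last neuron: genes only
        return genes
    return list(range(1, net.c + 1)) + genes


def _random_weight(node_id: int, C: int, cfg: GAConfig, rng: np.random.Generator) -> float:
    if node_id <= C:  # context input: non-negative
        return float(rng.uniform(0.0, cfg.w_max))
    return float(rng.uniform(cfg.w_min, cfg.w_max))


def _random_individual(
    P: int, C: int, c: int, target_gene: int, cfg: GAConfig, rng: np.random.Generator
) -> CandidateNetwork:
    net = CandidateNetwork(P=P, C=C, c=c, target_gene=target_gene, neurons=[])
    max_gene_inputs = min(3, P - 1)
    for position in range(1, c + 2):
        inputs: list[int] = []
        if position <= c:
            inputs.append(position)  # mandatory chain input x_position
            n_extra = int(rng.integers(0, max_gene_inputs + 1))
        else:
            n_extra = int(rng.integers(1, max_gene_inputs + 1))
        pool = [j for j in _allowed_inputs_static(P, C, c, target_gene, position)
                if j not in inputs]
        if n_extra > 0 and pool:
            extra = rng.choice(pool, size=min(n_extra, len(pool)), replace=False)
            inputs.extend(int(j) for j in extra)
        weights = [_random_weight(j, C, cfg, rng) for j in inputs]
        net.neurons.append(NeuronSpec(inputs, weights))
    if rng.random() < cfg.mu_init_prob:
        net.mu = float(rng.uniform(0.0, cfg.w_max))
    return net


def _allowed_inputs_static(P, C, c, target_gene, position):
    genes = [C + g for g in range(1, P + 1) if g != target_gene]
    if position == c + 1:
        return genes
    return list(range(1, c + 1)) + genes


def init_population(
    P: int,
    C: int,
    target_gene: int,
    cfg: GAConfig,
    rng: np.random.Generator | int | None = None,
) -> list[CandidateNetwork]:
    """Random initial population, stratified roughly uniformly over the
    number of context nodes c in {0..C}."""
    cfg.validate()
    rng = np.random.default_rng(rng)
    strata = rng.permutation(
        [i % (C + 1) for i in range(cfg.population_size)]
    )
    return [
        _random_individual(P, C, int(c), target_gene, cfg, rng) for c in strata
    ]


# ---------------------------------------------------------------------------
# selection and variation

def _score_of(fitness) -> float:
    return fitness.score if isinstance(fitness, FitnessReport) else float(fitness)


def _rank_key(population, fitnesses, i):
    """Deterministic ranking: fitness, then fewer leaves, then fewer
    neurons, then insertion order."""
    net = population[i]
    return (_score_of(fitnesses[i]), net.n_gene_leaves(), net.n_neurons, i)


def tournament_select(
    population: Sequence[CandidateNetwork],
    fitnesses: Sequence,
    cfg: GAConfig,
    rng: np.random.Generator | int | None = None,
    pool_size: int | None = None,
) -> list[CandidateNetwork]:
    """Fill a mating pool; each slot is the fittest of ``tournament_size``
    uniform draws (with replacement) from the population."""
    rng = np.random.default_rng(rng)
    n = len(population)
    if pool_size is None:
        pool_size = n - cfg.elite_count
    keys = [_rank_key(population, fitnesses, i) for i in range(n)]
    pool = []
    draws = rng.integers(0, n, size=(pool_size, cfg.tournament_size))
    for contenders in draws:
        winner = min(contenders, key=lambda i: keys[i])
        # a reference, not a copy: every downstream operator copies
        pool.append(population[int(winner)])
    return pool


def pair_for_crossover(
    pool: Sequence[CandidateNetwork],
    rng: np.random.Generator | int | None = None,
) -> tuple[list[tuple[CandidateNetwork, CandidateNetwork]], list[CandidateNetwork]]:
    """Shuffle the pool, stably sort by neuron count, and pair adjacent
    individuals with equal neuron counts; the rest pass through unpaired."""
    rng = np.random.default_rng(rng)
    order = rng.permutation(len(pool))
    shuffled = [pool[int(i)] for i in order]
    shuffled.sort(key=lambda net: net.n_neurons)  # stable
    pairs, passthrough = [], []
    i = 0
    while i < len(shuffled):
        if i + 1 < len(shuffled) and shuffled[i].n_neurons == shuffled[i + 1].n_neurons:
            pairs.append((shuffled[i], shuffled[i + 1]))
            i += 2
        else:
            passthrough.append(shuffled[i])
            i += 1
    return pairs, passthrough


def crossover(
    parent1: CandidateNetwork,
    parent2: CandidateNetwork,
    cfg: GAConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[CandidateNetwork, CandidateNetwork]:
    """With probability p_crossover, swap one whole neuron (inputs and
    weights) at a uniformly chosen position between two same-size parents;
    otherwise return copies.  The mandatory chain input occupies the same
    position in both parents, so the swap preserves the chain."""
    if parent1.n_neurons != parent2.n_neurons:
        raise ValueError("crossover requires parents with equal neuron counts")
    rng = np.random.default_rng(rng)
    child1, child2 = parent1.copy(), parent2.copy()
    if rng.random() < cfg.p_crossover:
        i = int(rng.integers(0, parent1.n_neurons))
        child1.neurons[i], child2.neurons[i] = child2.neurons[i], child1.neurons[i]
    return child1, child2


def _clip(w: float, lo: float, hi: float) -> float:
    return min(max(w, lo), hi)


def mutate(
    net: CandidateNetwork,
    cfg: GAConfig,
    rng: np.random.Generator | int | None = None,
) -> CandidateNetwork:
    """Per-site mutation with probability p_mutation per site.

    Sites: each neuron's input count (add a new allowed input with a fresh
    weight, or delete a random non-chain input), each non-chain input
    connection (rewire to an allowed node not already present), each weight
    (Gaussian perturbation clipped to the type's bounds), and the decay
    rate when present.  Infeasible mutations (no node to add, last input)
    are skipped.  The chain input is immune to deletion and rewiring and
    its weight stays non-negative.
    """
    rng = np.random.default_rng(rng)
    out = net.copy()
    pm = cfg.p_mutation
    for position, neuron in enumerate(out.neurons, start=1):
        chain_id = position if position <= out.c else None
        allowed = _allowed_inputs(out, position)
        # input-count site
        if rng.random() < pm:
            if rng.random() < 0.5:
                pool = [j for j in allowed if j not in neuron.input_ids]
                if pool:
                    j = int(pool[int(rng.integers(0, len(pool)))])
                    neuron.input_ids.append(j)
                    neuron.weights.append(_random_weight(j, out.C, cfg, rng))
            else:
                deletable = [
                    idx for idx, j in enumerate(neuron.input_ids) if j != chain_id
                ]
                if deletable and neuron.n_in > 1:
                    idx = int(deletable[int(rng.integers(0, len(deletable)))])
                    del neuron.input_ids[idx]
                    del neuron.weights[idx]
        # rewiring sites
        for idx in range(neuron.n_in):
            if neuron.input_ids[idx] == chain_id:
                continue
            if rng.random() < pm:
                pool = [j for j in allowed if j not in neuron.input_ids]
                if not pool:
                    continue
                j = int(pool[int(rng.integers(0, len(pool)))])
                w = neuron.weights[idx]
                if j <= out.C and w < 0:
                    w = float(rng.uniform(0.0, cfg.w_max))
                neuron.input_ids[idx] = j
                neuron.weights[idx] = w
        # weight sites
        for idx in range(neuron.n_in):
            if rng.random() < pm:
                w = neuron.weights[idx] + rng.normal(0.0, cfg.mutation_sd)
                if neuron.input_ids[idx] <= out.C:
                    neuron.weights[idx] = _clip(w, 0.0, cfg.w_max)
                else:
                    neuron.weights[idx] = _clip(w, cfg.w_min, cfg.w_max)
    if out.mu is not None and rng.random() < pm:
        out.mu = _clip(out.mu + rng.normal(0.0, cfg.mutation_sd), 0.0, cfg.w_max)
    return out


# ---------------------------------------------------------------------------
# main loop

def evolve(
    experiments: list[np.ndarray],
    target_gene: int,
    cfg: GAConfig | None = None,
    C: int = 3,
    burn_in: int | None = None,
    rng: np.random.Generator | int | None = None,
    check_invariants: bool = False,
) -> tuple[CandidateNetwork, EvolutionTrace]:
    """Evolve candidate networks for one target gene.

    ``experiments`` is a list of P x T expression matrices (already on the
    modelling scale).  Returns the all-time best individual and the trace.
    Terminates at max_generations or after stagnation_limit generations
    without improvement of the best fitness, whichever comes first.  All
    candidates are scored on the same evaluation window (burn_in defaults
    to C) so their information criteria are comparable.
    """
    cfg = cfg or GAConfig()
    cfg.validate()
    rng = np.random.default_rng(rng)
    P = int(np.asarray(experiments[0]).shape[0])
    if P < 2:
        raise ValueError("need at least 2 genes (no potential regulators)")
    if not (1 <= target_gene <= P):
        raise ValueError(f"target_gene={target_gene} outside 1..{P}")
    if burn_in is None:
        burn_in = C

    def evaluate(pop):
        return [evaluate_fitness(ind, experiments, burn_in=burn_in) for ind in pop]

    population = init_population(P, C, target_gene, cfg, rng)
    reports = evaluate(population)
    trace = EvolutionTrace()

    def keys_of(pop, reps):
        return [_rank_key(pop, reps, i) for i in range(len(pop))]

    keys = keys_of(population, reports)
    bi = min(range(len(population)), key=lambda i: keys[i])
    best_net, best_report = population[bi].copy(), reports[bi]
    stagnant = 0

    for gen in range(1, cfg.max_generations + 1):
        order = sorted(range(len(population)), key=lambda i: keys[i])
        elites = [population[i].copy() for i in order[: cfg.elite_count]]
        elite_reports = [reports[i] for i in order[: cfg.elite_count]]

        pool = tournament_select(population, reports, cfg, rng)
        pairs, passthrough = pair_for_crossover(pool, rng)
        children: list[CandidateNetwork] = []
        for a, b in pairs:
            c1, c2 = crossover(a, b, cfg, rng)
            children.extend((c1, c2))
        children.extend(passthrough)
        children = [mutate(ch, cfg, rng) for ch in children]

        population = elites + children
        reports = elite_reports + evaluate(children)

        if check_invariants:
            for ind in population:
                violations = validate(ind)
                if violations:
                    raise AssertionError(f"invalid individual: {violations}")

        keys = keys_of(population, reports)
        bi = min(range(len(population)), key=lambda i: keys[i])
        if reports[bi].score < best_report.score:
            best_net, best_report = population[bi].copy(), reports[bi]
            stagnant = 0
        else:
            # a tie with fewer regulators/neurons refines the incumbent but
            # does not count as fitness improvement
            if (_rank_key(population, reports, bi)[:3]
                    < (best_report.score, best_net.n_gene_leaves(),
                       best_net.n_neurons)):
                best_net, best_report = population[bi].copy(), reports[bi]
            stagnant += 1

        scores = [_score_of(r) for r in reports]
        finite = [s for s in scores if math.isfinite(s)]
        trace.records.append(
            GenerationRecord(
                generation=gen,
                best_fitness=best_report.score,
                mean_fitness=float(np.mean(finite)) if finite else math.inf,
                best_k=best_net.n_gene_leaves(),
                best_c=best_net.c,
            )
        )
        trace.best_per_generation.append(best_net.copy())

        if stagnant >= cfg.stagnation_limit:
            trace.termination = f"stagnation after {gen} generations"
            break
    else:
        trace.termination = f"max_generations ({cfg.max_generations})"
    return best_net, trace
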