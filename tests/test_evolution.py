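import math
from collections import Counter

import numpy as np
import pytest

from hrnn.evolution import (
    GAConfig,
    crossover,
    evolve,
    init_population,
    mutate,
    pair_for_crossover,
    tournament_select,
)
from hrnn.model import validate

from conftest import random_candidates


def small_cfg(**kw):
    defaults = dict(population_size=20, max_generations=10, stagnation_limit=5)
    defaults.update(kw)
    return GAConfig(**defaults)


# ---------------------------------------------------------------------------
# initialization

def test_init_population_all_valid_and_stratified():
    cfg = GAConfig(population_size=200)
    pop = init_population(6, 3, 2, cfg, rng=0)
    assert len(pop) == 200
    for net in pop:
        assert validate(net) == []
    counts = Counter(net.c for net in pop)
    assert set(counts) == {0, 1, 2, 3}
    assert all(count == 50 for count in counts.values())


def test_init_population_single_individual():
    cfg = GAConfig(population_size=1, elite_count=0)
    (net,) = init_population(4, 2, 1, cfg, rng=1)
    assert validate(net) == []


def test_init_population_exhaustive_validity_scan():
    cfg = GAConfig(population_size=1000)
    pop = init_population(5, 3, 3, cfg, rng=42)
    assert sum(bool(validate(net)) for net in pop) == 0


def test_config_validation():
    with pytest.raises(ValueError):
        GAConfig(p_crossover=1.5).validate()
    with pytest.raises(ValueError):
        GAConfig(w_min=1.0).validate()
    with pytest.raises(ValueError):
        GAConfig(population_size=2, elite_count=2).validate()


# ---------------------------------------------------------------------------
# selection

def test_degenerate_tournament_selects_global_best():
    pop = random_candidates(8, seed=1)
    fits = [float(i) for i in range(8)]  # individual 0 is best
    cfg = small_cfg(tournament_size=200, elite_count=0, population_size=8)
    pool = tournament_select(pop, fits, cfg, rng=0)
    assert all(ind is pop[0] for ind in pool)


def test_tournament_size_one_is_uniform_sampling():
    pop = random_candidates(5, seed=2)
    fits = [5.0, 4.0, 3.0, 2.0, 1.0]
    cfg = small_cfg(tournament_size=1, elite_count=0, population_size=5)
    pool = tournament_select(pop, fits, cfg, rng=3, pool_size=5000)
    freq = Counter(id(ind) for ind in pool)
    for ind in pop:
        assert freq[id(ind)] / 5000 == pytest.approx(0.2, abs=0.03)


def test_tournament_probability_matches_closed_form():
    """Two fitness classes, tournament of 3: the better class wins unless
    all three contenders are drawn from the worse class."""
    pop = random_candidates(10, seed=3)
    fits = [0.0] * 4 + [1.0] * 6  # 4 good, 6 bad
    cfg = small_cfg(tournament_size=3, elite_count=0, population_size=10)
    pool = tournament_select(pop, fits, cfg, rng=4, pool_size=100_000)
    good_ids = {id(pop[i]) for i in range(4)}
    p_good = sum(1 for ind in pool if id(ind) in good_ids) / 100_000
    assert p_good == pytest.approx(1 - 0.6**3, abs=0.01)


# ---------------------------------------------------------------------------
# pairing and crossover

def test_pairing_by_neuron_count():
    pool = random_candidates(40, C=3, seed=5)
    pairs, passthrough = pair_for_crossover(pool, rng=0)
    for a, b in pairs:
        assert a.n_neurons == b.n_neurons
    assert 2 * len(pairs) + len(passthrough) == 40


def test_all_distinct_sizes_pass_through():
    pool = [random_candidates(1, C=3, seed=c)[0] for c in range(2)]
    pool[0].c, pool[1].c = 0, 1  # rebuild sizes via init instead
    pop = []
    for c in (0, 1, 2, 3):
        cands = random_candidates(50, C=3, seed=c)
        pop.append(next(net for net in cands if net.c == c))
    pairs, passthrough = pair_for_crossover(pop, rng=1)
    assert pairs == [] and len(passthrough) == 4


def test_crossover_probability_zero_copies_parents():
    pool = random_candidates(50, C=2, seed=6)
    same = [n for n in pool if n.c == 1]
    a, b = same[0], same[1]
    cfg = small_cfg(p_crossover=0.0)
    c1, c2 = crossover(a, b, cfg, rng=0)
    assert c1.neurons[0].input_ids == a.neurons[0].input_ids
    assert c2.neurons[0].weights == b.neurons[0].weights
    assert c1 is not a and c2 is not b


def test_crossover_swaps_exactly_one_neuron():
    pops = random_candidates(200, C=3, seed=7)
    same_size = [n for n in pops if n.c == 2]
    a, b = same_size[0], same_size[1]
    cfg = small_cfg(p_crossover=1.0)
    c1, c2 = crossover(a, b, cfg, rng=9)
    swapped = [
        i for i in range(a.n_neurons)
        if c1.neurons[i].input_ids != a.neurons[i].input_ids
        or c1.neurons[i].weights != a.neurons[i].weights
    ]
    assert len(swapped) <= 1  # the drawn neuron may equal its counterpart
    for i in range(a.n_neurons):
        assert (c1.neurons[i].input_ids, c2.neurons[i].input_ids) in (
            (a.neurons[i].input_ids, b.neurons[i].input_ids),
            (b.neurons[i].input_ids, a.neurons[i].input_ids),
        )


def test_crossover_conservation_and_validity_scan():
    """Multiset of neuron specs is conserved and children stay valid over
    many random crossovers."""
    rng = np.random.default_rng(8)
    pool = random_candidates(400, C=3, seed=8)
    by_size = {}
    for net in pool:
        by_size.setdefault(net.n_neurons, []).append(net)
    cfg = small_cfg(p_crossover=0.9)
    done = 0
    for size, nets in by_size.items():
        for a, b in zip(nets[::2], nets[1::2]):
            c1, c2 = crossover(a, b, cfg, rng=rng)
            assert validate(c1) == [] and validate(c2) == []
            def specs(*nets):
                return Counter(
                    (tuple(n.input_ids), tuple(n.weights))
                    for net in nets for n in net.neurons
                )
            assert specs(a, b) == specs(c1, c2)
            done += 1
    assert done > 50


def test_crossover_rejects_unequal_sizes():
    pool = random_candidates(100, C=2, seed=9)
    a = next(n for n in pool if n.c == 0)
    b = next(n for n in pool if n.c == 2)
    with pytest.raises(ValueError):
        crossover(a, b, small_cfg(), rng=0)


# ---------------------------------------------------------------------------
# mutation

def test_mutation_probability_zero_is_identity():
    net = random_candidates(1, seed=10)[0]
    out = mutate(net, small_cfg(p_mutation=0.0), rng=0)
    assert out is not net
    assert [n.input_ids for n in out.neurons] == [n.input_ids for n in net.neurons]
    assert [n.weights for n in out.neurons] == [n.weights for n in net.neurons]
    assert out.mu == net.mu


def test_forced_mutation_perturbs_within_bounds():
    from hrnn.model import CandidateNetwork, NeuronSpec

    net = CandidateNetwork(
        P=2, C=0, c=0, target_gene=1, neurons=[NeuronSpec([2], [1.0])]
    )
    cfg = small_cfg(p_mutation=1.0, w_min=-2.0, w_max=2.0)
    changed = 0
    for s in range(20):
        out = mutate(net, cfg, rng=s)
        (w,) = out.neurons[0].weights if out.neurons[0].n_in == 1 else (None,)
        for neuron in out.neurons:
            for j, w in zip(neuron.input_ids, neuron.weights):
                assert -2.0 <= w <= 2.0
        changed += out.neurons[0].weights != net.neurons[0].weights
    assert changed == 20  # weight site always fires at p_mutation = 1


def test_mutation_mass_validity_scan():
    """10^4 mutations leave every network valid with all weights in
    bounds."""
    rng = np.random.default_rng(11)
    nets = random_candidates(500, P=5, C=3, target_gene=2, seed=11)
    cfg = small_cfg(p_mutation=0.3)
    for rep in range(20):
        for net in nets:
            out = mutate(net, cfg, rng=rng)
            assert validate(out) == []
    # bounds checked on a subsample
    for net in nets[:50]:
        out = mutate(net, cfg, rng=rng)
        for neuron in out.neurons:
            for j, w in zip(neuron.input_ids, neuron.weights):
                lo = 0.0 if j <= out.C else cfg.w_min
                assert lo <= w <= cfg.w_max


def test_chain_input_immune_to_removal():
    rng = np.random.default_rng(12)
    nets = [n for n in random_candidates(100, C=3, seed=12) if n.c >= 1]
    cfg = small_cfg(p_mutation=1.0)
    for net in nets[:30]:
        out = mutate(net, cfg, rng=rng)
        for pos in range(1, out.c + 1):
            assert pos in out.neurons[pos - 1].input_ids


# ---------------------------------------------------------------------------
# the generation loop

@pytest.fixture
def tiny_data(rng):
    from hrnn.synthetic import SimulationConfig, random_network, simulate_expression

    net = random_network(3, max_regulators=1, tau_max=2, rng=rng)
    X = simulate_expression(
        net, SimulationConfig(T=25, noise_variance=0.1), rng=rng
    )
    X = (X - X.min(axis=1, keepdims=True)) / np.ptp(X, axis=1, keepdims=True)
    return [X]


def test_elitism_makes_best_fitness_monotone(tiny_data):
    cfg = small_cfg(population_size=24, max_generations=12, elite_count=2,
                    stagnation_limit=12)
    _, trace = evolve(tiny_data, 1, cfg, C=2, rng=0)
    best = [r.best_fitness for r in trace.records]
    assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best, best[1:]))


def test_single_generation_returns_valid_best(tiny_data):
    cfg = small_cfg(population_size=10, max_generations=1)
    best, trace = evolve(tiny_data, 2, cfg, C=2, rng=1)
    assert validate(best) == []
    assert len(trace.records) == 1


def test_fixed_seed_bit_identical_trace(tiny_data):
    cfg = small_cfg(population_size=16, max_generations=8, stagnation_limit=8)
    b1, t1 = evolve(tiny_data, 1, cfg, C=2, rng=99)
    b2, t2 = evolve(tiny_data, 1, cfg, C=2, rng=99)
    assert [r.best_fitness for r in t1.records] == [r.best_fitness for r in t2.records]
    assert [r.mean_fitness for r in t1.records] == [r.mean_fitness for r in t2.records]
    assert b1.neurons[0].weights == b2.neurons[0].weights
    assert t1.termination == t2.termination


def test_every_generation_valid_in_debug_mode(tiny_data):
    cfg = small_cfg(population_size=14, max_generations=6, stagnation_limit=6)
    evolve(tiny_data, 1, cfg, C=2, rng=3, check_invariants=True)


def test_stagnation_terminates_early(tiny_data):
    cfg = small_cfg(population_size=10, max_generations=200, stagnation_limit=3,
                    p_mutation=0.0, p_crossover=0.0)
    _, trace = evolve(tiny_data, 1, cfg, C=2, rng=4)
    # without variation operators nothing improves: stop after 3 generations
    assert "stagnation" in trace.termination
    assert len(trace.records) <= 10


def test_tie_breaking_prefers_fewer_regulators():
    from hrnn.evolution import _rank_key
    from hrnn.model import CandidateNetwork, NeuronSpec

    lean = CandidateNetwork(P=3, C=0, c=0, target_gene=1,
                            neurons=[NeuronSpec([2], [1.0])])
    fat = CandidateNetwork(P=3, C=0, c=0, target_gene=1,
                           neurons=[NeuronSpec([2, 3], [1.0, 0.5])])
    pop = [fat, lean]
    fits = [5.0, 5.0]
    ranked = sorted(range(2), key=lambda i: _rank_key(pop, fits, i))
    assert ranked[0] == 1  # lean network wins the tie
    # equal everything: insertion order decides
    pop2 = [lean, lean.copy()]
    ranked2 = sorted(range(2), key=lambda i: _rank_key(pop2, fits, i))
    assert ranked2 == [0, 1]
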