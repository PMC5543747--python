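"""Synthetic time-delayed GRN benchmarks.

Random ground-truth networks (each gene gets 1..max_regulators regulators,
integer delays up to tau_max, signed effects) and simulated time-course
expression from either of two generating models:

linear      G_i(t+1) = sum_j a_ij * G_j(t - tau_ij) + eps_i(t)
nonlinear   G_i(t+1) = sum_j f(a_ij * G_j(t - tau_ij)) + eps_i(t)

with f the logistic function and eps_i(t) ~ N(0, sigma^2).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model import _expit, sigmoid

__all__ = [
    "TrueEdge",
    "TrueNetwork",
    "SimulationConfig",
    "SimulationDivergenceError",
    "random_network",
    "simulate_expression",
    "generate_benchmark",
    "BenchmarkCase",
]

#: reject linear trajectories whose magnitude exceeds this bound
DIVERGENCE_BOUND = 1e6
#: re-simulation attempts before declaring a network divergent
MAX_REJECTIONS = 100


@dataclass(frozen=True)
class TrueEdge:
    """Ground-truth interaction: gene `regulator` acts on gene `target`
    (1-based indices) with signed strength `effect` after `delay` steps."""

    regulator: int
    target: int
    delay: int
    effect: float


@dataclass
class TrueNetwork:
    P: int
    tau_max: int
    edges: list[TrueEdge]

    def regulators_of(self, target: int) -> list[TrueEdge]:
        return [e for e in self.edges if e.target == target]

    def in_degrees(self) -> list[int]:
        return [len(self.regulators_of(i)) for i in range(1, self.P + 1)]


class SimulationDivergenceError(RuntimeError):
    """Raised when a network's trajectory exceeds the divergence bound on
    every re-simulation attempt."""


@dataclass
class SimulationConfig:
    """Conditions of one simulated experiment.

    T time points; Gaussian noise with variance ``noise_variance`` on every
    generated point; ``model`` chooses the linear or nonlinear update;
    initial values drawn uniformly from [init_low, init_high].
    """

    T: int = 50
    noise_variance: float = 1.0
    model: str = "nonlinear"
    init_low: float = 0.0
    init_high: float = 1.0

    def validate(self, tau_max: int) -> None:
        if self.model not in ("linear", "nonlinear"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.noise_variance < 0:
            raise ValueError("noise variance must be >= 0")
        if self.T < tau_max + 2:
            raise ValueError(f"T={self.T} too short for tau_max={tau_max}")


def random_network(
    P: int,
    max_regulators: int = 3,
    tau_max: int = 4,
    rng: np.random.Generator | int | None = None,
    allow_self_loops: bool = False,
    effect_low: float = 0.25,
    effect_high: float = 1.0,
) -> TrueNetwork:
    """Draw a random ground-truth network.

    Every gene receives between 1 and ``max_regulators`` regulators (count
    uniform), drawn uniformly without replacement from the other genes;
    delays are uniform on {1..tau_max}; effect magnitudes are uniform on
    [effect_low, effect_high] with equiprobable random sign, so no effect is
    negligibly small.
    """
    if P < 2:
        raise ValueError("need at least 2 genes")
    pool_size = P if allow_self_loops else P - 1
    if not (1 <= max_regulators <= pool_size):
        raise ValueError(
            f"max_regulators={max_regulators} must be in 1..{pool_size} for P={P}"
        )
    rng = np.random.default_rng(rng)
    edges: list[TrueEdge] = []
    for target in range(1, P + 1):
        candidates = [g for g in range(1, P + 1) if allow_self_loops or g != target]
        n_reg = int(rng.integers(1, max_regulators + 1))
        regs = rng.choice(candidates, size=n_reg, replace=False)
        for reg in regs:
            delay = int(rng.integers(1, tau_max + 1))
            magnitude = rng.uniform(effect_low, effect_high)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            edges.append(TrueEdge(int(reg), target, delay, float(sign * magnitude)))
    return TrueNetwork(P=P, tau_max=tau_max, edges=edges)


def _simulate_once(
    net: TrueNetwork, cfg: SimulationConfig, rng: np.random.Generator,
    initial: np.ndarray | None,
) -> np.ndarray:
    P, T, tau = net.P, cfg.T, net.tau_max
    n_init = tau  # the earliest computed point looks back at most tau_max columns
    X = np.empty((P, T))
    if initial is None:
        X[:, :n_init] = rng.uniform(cfg.init_low, cfg.init_high, size=(P, n_init))
    else:
        X[:, :n_init] = initial
    sd = np.sqrt(cfg.noise_variance)
    # per-target regulator arrays for vectorized inner products
    by_target = [net.regulators_of(i) for i in range(1, P + 1)]
    regs = [np.array([e.regulator - 1 for e in lst]) for lst in by_target]
    lags = [np.array([e.delay for e in lst]) for lst in by_target]
    effs = [np.array([e.effect for e in lst]) for lst in by_target]
    nonlinear = cfg.model == "nonlinear"
    for t in range(n_init, T):
        noise = rng.normal(0.0, sd, size=P) if sd > 0 else np.zeros(P)
        for i in range(P):
            vals = X[regs[i], t - lags[i]]
            if nonlinear:
                X[i, t] = np.sum(_expit(effs[i] * vals)) + noise[i]
            else:
                X[i, t] = np.dot(effs[i], vals) + noise[i]
    return X


def simulate_expression(
    net: TrueNetwork,
    cfg: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    initial: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate a P x T expression matrix from a ground-truth network.

    An edge with delay tau means the regulator's value tau steps back
    drives the target's next value: G_i(t+1) depends on G_j(t+1-tau), so
    tau = 1 is direct one-step regulation.  The first ``tau_max`` time
    points are initial values (uniform on the configured range), so that
    every delayed term is defined from the first computed point on.  Linear trajectories exceeding the divergence bound
    are rejected and re-simulated with fresh draws up to MAX_REJECTIONS
    times; a network that always diverges raises SimulationDivergenceError.
    """
    cfg.validate(net.tau_max)
    rng = np.random.default_rng(rng)
    for _ in range(MAX_REJECTIONS):
        X = _simulate_once(net, cfg, rng, initial)
        if np.all(np.isfinite(X)) and np.max(np.abs(X)) <= DIVERGENCE_BOUND:
            return X
        if initial is not None:
            break  # fixed initial values cannot be redrawn
    raise SimulationDivergenceError(
        f"trajectory exceeded {DIVERGENCE_BOUND:g} in all attempts "
        f"(P={net.P}, model={cfg.model})"
    )


@dataclass
class BenchmarkCase:
    """One replicate of one benchmark condition."""

    P: int
    noise_variance: float
    replicate: int
    seed: int
    network: TrueNetwork
    expression: np.ndarray


def generate_benchmark(
    P_list: Sequence[int],
    sigma2_list: Sequence[float],
    replicates: int,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    max_regulators: int = 3,
    tau_max: int = 4,
) -> list[BenchmarkCase]:
    """Generate the benchmark suite: for every (P, sigma^2) pair,
    ``replicates`` independent (network, expression) cases.

    Fully reproducible from the master seed: each case gets a recorded
    sub-seed.  A network whose linear dynamics diverge on every simulation
    attempt is replaced by a freshly drawn network (unstable linear systems
    are uninformative benchmarks).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    template = cfg or SimulationConfig()
    master = np.random.default_rng(seed)
    cases: list[BenchmarkCase] = []
    for P in P_list:
        for sigma2 in sigma2_list:
            for rep in range(replicates):
                case_cfg = dataclasses.replace(template, noise_variance=float(sigma2))
                for _attempt in range(MAX_REJECTIONS):
                    sub_seed = int(master.integers(0, 2**31 - 1))
                    sub_rng = np.random.default_rng(sub_seed)
                    net = random_network(
                        P, max_regulators=max_regulators, tau_max=tau_max, rng=sub_rng
                    )
                    try:
                        X = simulate_expression(net, case_cfg, sub_rng)
                    except SimulationDivergenceError:
                        continue
                    cases.append(
                        BenchmarkCase(P, float(sigma2), rep, sub_seed, net, X)
                    )
                    break
                else:
                    raise SimulationDivergenceError(
                        f"no stable network found for P={P}, sigma2={sigma2}"
                    )
    return cases
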