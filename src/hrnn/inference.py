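"""Whole-network inference: decoupled per-target training.

One evolutionary run per target gene; the union of the extracted edges is
the inferred network.  `HRNNInference` is a scikit-learn style estimator
(fit on time x genes data, fitted attributes with trailing underscores)
that composes with sklearn tooling; `infer_grn` is a thin functional
wrapper over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .evolution import EvolutionTrace, GAConfig, evolve
from .fitness import FitnessReport, evaluate_fitness
from .model import RegulatoryEdge, extract_edges

__all__ = [
    "ExpressionDataset",
    "InferredGRN",
    "NormalizedExpression",
    "normalize_expression",
    "HRNNInference",
    "infer_grn",
    "edges_to_frame",
]


@dataclass
class ExpressionDataset:
    """Multi-experiment time-course expression.

    ``experiments`` holds one P x T_l matrix per experiment, with a shared
    gene order given by ``gene_names``.
    """

    gene_names: list[str]
    experiments: list[np.ndarray]

    def __post_init__(self) -> None:
        self.gene_names = [str(g) for g in self.gene_names]
        self.experiments = [np.asarray(X, dtype=float) for X in self.experiments]
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("duplicate gene names")
        if not self.experiments:
            raise ValueError("at least one experiment required")
        P = len(self.gene_names)
        for l, X in enumerate(self.experiments):
            if X.ndim != 2 or X.shape[0] != P:
                raise ValueError(
                    f"experiment {l}: expected {P} x T matrix, got {X.shape}"
                )
            if X.shape[1] < 3:
                raise ValueError(f"experiment {l}: fewer than 3 time points")
            if not np.all(np.isfinite(X)):
                raise ValueError(f"experiment {l}: non-finite values")

    @property
    def P(self) -> int:
        return len(self.gene_names)

    @property
    def L(self) -> int:
        return len(self.experiments)


@dataclass
class NormalizedExpression:
    """Min-max scaled dataset plus what is needed to undo the scaling."""

    dataset: ExpressionDataset
    mins: list[np.ndarray]
    maxs: list[np.ndarray]
    constant_genes: list[list[str]]

    def restore(self) -> ExpressionDataset:
        """Inverse transform back to the original scale."""
        experiments = []
        for X, lo, hi in zip(self.dataset.experiments, self.mins, self.maxs):
            span = hi - lo
            restored = X * span[:, None] + lo[:, None]
            const = span == 0
            restored[const] = lo[const, None]
            experiments.append(restored)
        return ExpressionDataset(self.dataset.gene_names, experiments)


def normalize_expression(data: ExpressionDataset) -> NormalizedExpression:
    """Min-max scale each gene to [0, 1] within each experiment.

    The sigmoid output range makes raw-scale targets unreachable, so all
    modelling happens on this scale.  A constant gene maps to 0.5 and is
    flagged (and warned about): it carries no temporal signal.
    """
    experiments, mins, maxs, flagged = [], [], [], []
    for l, X in enumerate(data.experiments):
        lo = X.min(axis=1)
        hi = X.max(axis=1)
        span = hi - lo
        const = span == 0
        safe = np.where(const, 1.0, span)
        Xn = (X - lo[:, None]) / safe[:, None]
        Xn[const] = 0.5
        names = [data.gene_names[i] for i in np.flatnonzero(const)]
        if names:
            warnings.warn(
                f"experiment {l}: constant gene(s) {names} mapped to 0.5",
                RuntimeWarning,
                stacklevel=2,
            )
        experiments.append(Xn)
        mins.append(lo)
        maxs.append(hi)
        flagged.append(names)
    return NormalizedExpression(
        ExpressionDataset(data.gene_names, experiments), mins, maxs, flagged
    )


@dataclass
class InferredGRN:
    """The assembled network plus per-target diagnostics and provenance."""

    edges: list[RegulatoryEdge]
    gene_names: list[str]
    fitness_reports: dict[str, FitnessReport]
    traces: dict[str, EvolutionTrace]
    target_seeds: dict[str, int]
    params: dict

    def to_frame(self) -> pd.DataFrame:
        return edges_to_frame(self.edges)


def edges_to_frame(edges: Sequence[RegulatoryEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "regulator": e.regulator,
                "target": e.target,
                "delay": e.delay,
                "sign": e.sign,
                "weight": e.weight,
            }
            for e in edges
        ],
        columns=["regulator", "target", "delay", "sign", "weight"],
    )


def _as_dataset(X, gene_names=None) -> ExpressionDataset:
    if isinstance(X, ExpressionDataset):
        return X
    if isinstance(X, pd.DataFrame):
        # samples x features convention: rows are time points
        return ExpressionDataset(list(X.columns), [X.to_numpy().T])
    if isinstance(X, np.ndarray):
        X = [X]
    mats = [np.asarray(m, dtype=float).T for m in X]  # time x genes -> genes x time
    P = mats[0].shape[0]
    if gene_names is None:
        gene_names = [f"G{i}" for i in range(1, P + 1)]
    return ExpressionDataset(list(gene_names), mats)


class HRNNInference(BaseEstimator):
    """Infer a time-delayed, signed, directed GRN from time-course data.

    For each gene in turn, a population of chain-structured recurrent
    networks is evolved by a genetic algorithm under an AIC/AICc fitness
    (goodness of fit vs. number of regulator leaves); the edges read off
    the per-target winners are unioned into the network.  An edge j -> i
    with delay d and sign s means gene j acts on gene i after d time steps,
    activating (s = +1) or repressing (s = -1).

    Parameters
    ----------
    max_delay : maximum reportable regulation delay; the candidate networks
        use up to ``max_delay - 1`` context nodes.
    population_size, max_generations, p_crossover, p_mutation,
    tournament_size, elite_count, w_min, w_max, mutation_sd,
    stagnation_limit : genetic-algorithm hyperparameters, see
        :class:`~hrnn.evolution.GAConfig`.
    burn_in : evaluation starts after this many time points (default:
        ``max_delay - 1`` so every candidate's context chain has filled).
    n_restarts : independent evolutionary runs per target; the winner with
        the best fitness is kept.  Multi-start search is the standard
        remedy for the multimodal landscapes of evolved network topologies.
    mu_threshold : decay rates above this report a repressive self-edge.
    min_weight : optional magnitude filter on reported edges (0 = keep all;
        the information-criterion penalty is the primary sparsity control).
    random_state : master seed; per-target sub-seeds are derived from it,
        making runs reproducible and target-wise restartable.

    Attributes
    ----------
    edges_ : list of RegulatoryEdge for the whole network.
    network_ : InferredGRN with per-target fitness reports and GA traces.
    gene_names_ : gene order used during fitting.

    Examples
    --------
    >>> est = HRNNInference(max_delay=2, population_size=30,
    ...                     max_generations=20, random_state=0)
    >>> est.fit(X)                    # X: time points x genes array
    >>> est.edges_frame_.head()
    """

    def __init__(
        self,
        max_delay: int = 4,
        population_size: int = 100,
        max_generations: int = 200,
        p_crossover: float = 0.7,
        p_mutation: float = 0.1,
        tournament_size: int = 3,
        elite_count: int = 2,
        w_min: float = -5.0,
        w_max: float = 5.0,
        mutation_sd: float = 0.5,
        stagnation_limit: int = 50,
        burn_in: int | None = None,
        n_restarts: int = 2,
        mu_threshold: float = 0.01,
        min_weight: float = 0.0,
        normalize: bool = True,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.max_delay = max_delay
        self.population_size = population_size
        self.max_generations = max_generations
        self.p_crossover = p_crossover
        self.p_mutation = p_mutation
        self.tournament_size = tournament_size
        self.elite_count = elite_count
        self.w_min = w_min
        self.w_max = w_max
        self.mutation_sd = mutation_sd
        self.stagnation_limit = stagnation_limit
        self.burn_in = burn_in
        self.n_restarts = n_restarts
        self.mu_threshold = mu_threshold
        self.min_weight = min_weight
        self.normalize = normalize
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _ga_config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            max_generations=self.max_generations,
            p_crossover=self.p_crossover,
            p_mutation=self.p_mutation,
            tournament_size=self.tournament_size,
            elite_count=self.elite_count,
            w_min=self.w_min,
            w_max=self.w_max,
            mutation_sd=self.mutation_sd,
            stagnation_limit=self.stagnation_limit,
        )

    @staticmethod
    def _target_seed(master: int, target_index: int, restart: int = 0) -> int:
        """Deterministic per-target (and per-restart) sub-seed derived from
        the master seed."""
        ss = np.random.SeedSequence(
            entropy=int(master), spawn_key=(target_index, restart)
        )
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))

    def fit(self, X, y=None, gene_names: Sequence[str] | None = None):
        """Fit on time-course data.

        X may be an ExpressionDataset, a (time points x genes) array or
        DataFrame, or a list of such arrays (one per experiment).
        """
        if self.max_delay < 1:
            raise ValueError("max_delay must be >= 1")
        data = _as_dataset(X, gene_names)
        if data.P < 2:
            raise ValueError("need at least 2 genes (no potential regulators)")
        C = self.max_delay - 1
        burn_in = C if self.burn_in is None else self.burn_in
        if self.random_state is None:
            # draw a concrete master seed so provenance is recordable
            self._master_seed_ = int(
                np.random.SeedSequence().generate_state(1, dtype=np.uint32)[0]
            )
        else:
            self._master_seed_ = int(self.random_state)

        norm = normalize_expression(data) if self.normalize else None
        experiments = (norm.dataset if norm else data).experiments
        cfg = self._ga_config()

        edges: list[RegulatoryEdge] = []
        reports: dict[str, FitnessReport] = {}
        traces: dict[str, EvolutionTrace] = {}
        seeds: dict[str, int] = {}
        n_restarts = max(1, int(self.n_restarts))
        for t_idx, name in enumerate(data.gene_names, start=1):
            seed = self._target_seed(self._master_seed_, t_idx)
            seeds[name] = seed
            best = trace = best_report = None
            try:
                for restart in range(n_restarts):
                    sub = self._target_seed(self._master_seed_, t_idx, restart)
                    cand, cand_trace = evolve(
                        experiments, t_idx, cfg, C=C, burn_in=burn_in,
                        rng=np.random.default_rng(sub),
                    )
                    rep = evaluate_fitness(cand, experiments, burn_in=burn_in)
                    if best_report is None or rep.score < best_report.score:
                        best, trace, best_report = cand, cand_trace, rep
            except Exception as exc:  # a failed target is skipped, not fatal
                warnings.warn(
                    f"target {name}: evolution failed ({exc}); skipped",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            reports[name] = best_report
            traces[name] = trace
            target_edges = extract_edges(best, data.gene_names, self.mu_threshold)
            if self.min_weight > 0:
                target_edges = [
                    e for e in target_edges if abs(e.weight) >= self.min_weight
                ]
            edges.extend(target_edges)
            if self.verbose:
                print(
                    f"[hrnn] target {name}: fitness {reports[name].score:.3f}, "
                    f"{len(target_edges)} edge(s), {trace.termination}"
                )

        # drop duplicate (regulator, target, delay) triples, keep first
        seen = set()
        unique: list[RegulatoryEdge] = []
        for e in edges:
            key = (e.regulator, e.target, e.delay)
            if key not in seen:
                seen.add(key)
                unique.append(e)

        self.gene_names_ = list(data.gene_names)
        self.edges_ = unique
        self.network_ = InferredGRN(
            edges=unique,
            gene_names=self.gene_names_,
            fitness_reports=reports,
            traces=traces,
            target_seeds=seeds,
            params=self.get_params(),
        )
        return self

    @property
    def edges_frame_(self) -> pd.DataFrame:
        return edges_to_frame(self.edges_)


def infer_grn(
    data: ExpressionDataset,
    seed: int | None = None,
    **params,
) -> InferredGRN:
    """Functional entry point: fit an :class:`HRNNInference` and return the
    inferred network."""
    est = HRNNInference(random_state=seed, **params)
    est.fit(data)
    return est.network_
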