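"""Hierarchical recurrent network candidates and their dynamics.

A candidate models one target gene.  The network is a chain of ``c + 1``
neurons: neuron 1 outputs the (predicted) target gene, and neuron ``i + 1``
outputs context node ``x_i``, which is a mandatory input of neuron ``i``.
Context nodes carry no experimental measurement; each hop along the chain
delays information by one time step, so a gene entering neuron ``d`` acts on
the target with delay ``d``.

Node indexing is 1-based: nodes ``1..C`` are context nodes, nodes
``C+1..C+P`` are genes (matching the x1..x8 layout with C=3, P=5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NeuronSpec",
    "CandidateNetwork",
    "RegulatoryEdge",
    "sigmoid",
    "validate",
    "step",
    "simulate_target",
    "extract_edges",
]


def sigmoid(x):
    """Logistic function 1 / (1 + exp(-x)), the neuron transfer function.

    Monotonically increasing with range (0, 1); satisfies f(0) = 0.5 and
    f(-x) = 1 - f(x).  Saturates (never overflows) for large |x|.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def _expit(z: np.ndarray) -> np.ndarray:
    # hot-loop logistic: clipping keeps exp() in range, result identical to
    # sigmoid() to double precision for |z| <= 500 and saturated beyond
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


@dataclass
class NeuronSpec:
    """Inputs of one neuron: node indices and aligned connection weights."""

    input_ids: list[int]
    weights: list[float]

    def copy(self) -> "NeuronSpec":
        return NeuronSpec(list(self.input_ids), list(self.weights))

    @property
    def n_in(self) -> int:
        return len(self.input_ids)


@dataclass
class CandidateNetwork:
    """GA genome: an evolvable chain-structured recurrent network.

    Parameters
    ----------
    P, C : gene count and maximum number of context nodes.
    c : number of context nodes actually used (0 <= c <= C); the network
        then has ``c + 1`` neurons.
    target_gene : 1-based gene index in ``1..P``; node id ``C + target_gene``.
    neurons : neuron 1 first (outputs the target), neuron ``i+1`` outputs
        context node ``x_i``.
    mu : optional decay rate modelling the target's suppression of its own
        expression; ``None`` when the genome carries no decay term.
    """

    P: int
    C: int
    c: int
    target_gene: int
    neurons: list[NeuronSpec]
    mu: float | None = None

    # -- derived helpers -------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def target_node(self) -> int:
        return self.C + self.target_gene

    def copy(self) -> "CandidateNetwork":
        return CandidateNetwork(
            self.P, self.C, self.c, self.target_gene,
            [n.copy() for n in self.neurons], self.mu,
        )

    def gene_leaf_ids(self) -> list[int]:
        """All gene node ids appearing as inputs, in neuron order (with repeats)."""
        out = []
        for neuron in self.neurons:
            out.extend(j for j in neuron.input_ids if j > self.C)
        return out

    def n_gene_leaves(self) -> int:
        """k of the information criterion: gene leaf nodes (a gene entering
        several neurons contributes one leaf per entry)."""
        n = 0
        for neuron in self.neurons:
            for j in neuron.input_ids:
                if j > self.C:
                    n += 1
        return n

    def n_distinct_regulators(self) -> int:
        """Distinct regulator genes among the leaves."""
        return len(set(self.gene_leaf_ids()))


@dataclass(frozen=True)
class RegulatoryEdge:
    """A directed, signed, delayed regulatory interaction."""

    regulator: str
    target: str
    delay: int
    sign: int
    weight: float


def validate(net: CandidateNetwork) -> list[str]:
    """Return a list of structural-constraint violations (empty iff valid).

    Enforced constraints: exactly ``c + 1`` neurons; the mandatory chain
    input (context ``x_i`` into neuron ``i``); no context inputs on the last
    neuron; non-negative weights on context inputs; no duplicate inputs; the
    target gene never an input; only the first ``c`` context nodes usable.
    """
    v: list[str] = []
    if not (0 <= net.c <= net.C):
        v.append(f"c={net.c} outside [0, C={net.C}]")
    if net.n_neurons != net.c + 1:
        v.append(f"{net.n_neurons} neurons for c={net.c} (expected {net.c + 1})")
    if not (1 <= net.target_gene <= net.P):
        v.append(f"target_gene={net.target_gene} outside 1..{net.P}")
    if net.mu is not None and net.mu < 0:
        v.append(f"negative decay rate mu={net.mu}")
    for pos, neuron in enumerate(net.neurons, start=1):
        if len(neuron.input_ids) != len(neuron.weights):
            v.append(f"neuron {pos}: input/weight length mismatch")
            continue
        if neuron.n_in < 1:
            v.append(f"neuron {pos}: no inputs")
        if len(set(neuron.input_ids)) != len(neuron.input_ids):
            v.append(f"neuron {pos}: duplicate input ids")
        for j, w in zip(neuron.input_ids, neuron.weights):
            if not (1 <= j <= net.C + net.P):
                v.append(f"neuron {pos}: input id {j} out of range")
            elif net.c < j <= net.C:
                v.append(f"neuron {pos}: input {j} is an unused context node")
            if j == net.target_node:
                v.append(f"neuron {pos}: target gene used as input")
            if j <= net.C and w < 0:
                v.append(f"neuron {pos}: negative weight {w} on context input {j}")
        if pos == net.n_neurons:
            ctx = [j for j in neuron.input_ids if j <= net.C]
            if ctx:
                v.append(f"neuron {pos} (last): context inputs {ctx} not allowed")
        if pos <= net.c and pos not in neuron.input_ids:
            v.append(f"neuron {pos}: mandatory chain input x_{pos} missing")
    return v


def _check_finite(values: np.ndarray) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite node values passed to step")


def step(net: CandidateNetwork, node_values: Sequence[float]) -> np.ndarray:
    """One synchronous update t -> t+1 of all neuron outputs.

    ``node_values`` holds the value of every node (1-based ids ``1..C+P``,
    passed as a length ``C+P`` sequence) at time t.  Returns the length
    ``c + 1`` vector ``[target(t+1), x_1(t+1), ..., x_c(t+1)]``.  Gene
    values are external drivers and are never modified here.  When a decay
    rate is present the target output additionally subtracts
    ``mu * target(t)`` and is clipped below at 0.
    """
    vals = np.asarray(node_values, dtype=float)
    if vals.shape != (net.C + net.P,):
        raise ValueError(f"expected {net.C + net.P} node values, got {vals.shape}")
    _check_finite(vals)
    out = np.empty(net.n_neurons)
    for k, neuron in enumerate(net.neurons):
        z = 0.0
        for j, w in zip(neuron.input_ids, neuron.weights):
            z += w * vals[j - 1]
        out[k] = sigmoid(z)
    if net.mu is not None:
        out[0] = max(0.0, out[0] - net.mu * vals[net.target_node - 1])
    return out


def compile_weights(net: CandidateNetwork) -> np.ndarray:
    """Dense (c+1) x (c+P) weight matrix for fast simulation.

    Columns 0..c-1 are the used context nodes x_1..x_c, columns c..c+P-1
    the genes G_1..G_P.  Row k is neuron k+1.
    """
    W = np.zeros((net.n_neurons, net.c + net.P))
    for k, neuron in enumerate(net.neurons):
        for j, w in zip(neuron.input_ids, neuron.weights):
            if j <= net.C:
                W[k, j - 1] += w
            else:
                W[k, net.c + (j - net.C - 1)] += w
    return W


def simulate_target(
    net: CandidateNetwork,
    data: np.ndarray,
    burn_in: int | None = None,
) -> np.ndarray:
    """Teacher-forced prediction of the target trajectory.

    Gene inputs are driven by the observed ``data`` (shape P x T) at every
    step; context nodes start at 0.5 (the sigmoid midpoint) at t=1 and
    evolve freely.  Returns predictions for t in {start+1, ..., T} where
    ``start = max(burn_in, 1)`` (the value at t=1 is never predictable as it
    has no predecessor).  ``burn_in`` defaults to ``c`` and must be >= ``c``
    so the context chain has filled before evaluation.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] != net.P:
        raise ValueError(f"data must be P x T with P={net.P}, got {data.shape}")
    _check_finite(data)
    T = data.shape[1]
    if burn_in is None:
        burn_in = net.c
    if burn_in < net.c:
        raise ValueError(f"burn_in={burn_in} < c={net.c}")
    start = max(burn_in, 1)
    if T <= start:
        raise ValueError(f"series of length {T} too short for burn_in={burn_in}")

    c = net.c
    mu = 0.0 if net.mu is None else net.mu
    tcol = net.target_gene - 1
    W = compile_weights(net)

    if c == 0:
        # feed-forward special case: vectorize across all time steps
        z = W[0, :] @ data[:, :-1]
        preds = _expit(z)
        if mu:
            preds = np.maximum(0.0, preds - mu * data[tcol, :-1])
        return preds[start - 1:]

    # When every neuron k+1 (row k >= 1) reads only contexts produced by
    # deeper neurons (x_j with j > k; the chain input x_{k+1} always
    # qualifies), the context trajectories resolve in topological order and
    # each one vectorizes across time.  Only genuinely recurrent context
    # links (a neuron reading a shallower context) need the stepwise loop.
    acyclic = all(
        not np.any(W[k, :k]) for k in range(1, c + 1)
    )
    if acyclic:
        # CT[j-1, i] = x_j at time t=i+1 (1-based), i = 0..T-2
        CT = np.empty((c, T - 1))
        for k in range(c, 0, -1):  # row k outputs x_k
            CT[k - 1, 0] = 0.5
            if T > 2:
                z = W[k, c:] @ data[:, : T - 2]
                if np.any(W[k, k:c]):
                    z = z + W[k, k:c] @ CT[k:, : T - 2]
                CT[k - 1, 1:] = _expit(z)
        z = W[0, c:] @ data[:, : T - 1] + W[0, :c] @ CT
        preds = _expit(z)
        if mu:
            preds = np.maximum(0.0, preds - mu * data[tcol, : T - 1])
        return preds[start - 1:]

    u = np.empty(c + net.P)
    ctx = np.full(c, 0.5)
    preds = np.empty(T - 1)
    for t in range(T - 1):  # 0-based column t drives prediction at t+1
        u[:c] = ctx
        u[c:] = data[:, t]
        out = _expit(W @ u)
        tgt = out[0] - mu * data[tcol, t]
        preds[t] = tgt if tgt > 0.0 else 0.0
        ctx = out[1:]
    return preds[start - 1:]


def extract_edges(
    net: CandidateNetwork,
    gene_names: Sequence[str],
    mu_threshold: float = 0.01,
) -> list[RegulatoryEdge]:
    """Read the regulatory interactions off a (trained) candidate network.

    A gene input of neuron ``d`` regulates the target with delay ``d`` (one
    time step per chain hop); the sign is the sign of the leaf weight.
    Recurrent context-to-context links shape the dynamics but add no edges
    (shortest-path convention).  A decay rate above ``mu_threshold`` is
    reported as a repressive self-edge with delay 1.
    """
    if len(gene_names) != net.P:
        raise ValueError(f"expected {net.P} gene names, got {len(gene_names)}")
    target_name = gene_names[net.target_gene - 1]
    edges: list[RegulatoryEdge] = []
    for d, neuron in enumerate(net.neurons, start=1):
        for j, w in zip(neuron.input_ids, neuron.weights):
            if j <= net.C:
                continue
            edges.append(
                RegulatoryEdge(
                    regulator=gene_names[j - net.C - 1],
                    target=target_name,
                    delay=d,
                    sign=1 if w >= 0 else -1,
                    weight=float(w),
                )
            )
    if net.mu is not None and net.mu > mu_threshold:
        edges.append(
            RegulatoryEdge(
                regulator=target_name,
                target=target_name,
                delay=1,
                sign=-1,
                weight=-float(net.mu),
            )
        )
    return edges
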