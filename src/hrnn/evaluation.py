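"""Scoring inferred networks against ground truth.

Three nested correctness criteria for a directed edge:

* Link   — the (regulator, target) pair and its direction are correct;
* Delay  — the link is correct and the time delay matches exactly;
* Effect — the link is correct and the sign of the effect matches.

Each is summarized by TP/FP/FN counts and precision / recall / F-score.
Aggregation helpers reproduce benchmark-table statistics: per-condition
means, two-sample t-tests with multiplicative p-value adjustment, and a
linear trend fit of F-score against a condition variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "CriterionScores",
    "CRITERIA",
    "score",
    "score_all",
    "precision_recall_f",
    "aggregate",
    "compare_methods",
    "trend_fit",
    "truncate2",
]

CRITERIA = ("link", "delay", "effect")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class CriterionScores:
    criterion: str
    counts: ConfusionCounts
    precision: float
    recall: float
    f_score: float
    degenerate: bool = False  # flagged when a zero division yielded 0


def truncate2(x: float) -> float:
    """Two-decimal truncation used for table formatting (6/9 -> 0.66)."""
    return math.floor(x * 100.0) / 100.0


def _edge_fields(edge) -> tuple[str, str, int, int]:
    """(regulator, target, delay, sign) from any edge-like record."""
    if isinstance(edge, dict):
        reg, tgt = edge["regulator"], edge["target"]
        delay = edge.get("delay")
        sign = edge.get("sign")
        if sign is None and "effect" in edge:
            sign = 1 if edge["effect"] >= 0 else -1
        if sign is None and "weight" in edge:
            sign = 1 if edge["weight"] >= 0 else -1
    else:
        reg = getattr(edge, "regulator")
        tgt = getattr(edge, "target")
        delay = getattr(edge, "delay", None)
        sign = getattr(edge, "sign", None)
        if sign is None:
            eff = getattr(edge, "effect", None)
            if eff is None:
                eff = getattr(edge, "weight", None)
            sign = None if eff is None else (1 if eff >= 0 else -1)
    return str(reg), str(tgt), delay, sign


def _as_records(edges) -> list[tuple[str, str, int, int]]:
    if isinstance(edges, pd.DataFrame):
        edges = edges.to_dict("records")
    return [_edge_fields(e) for e in edges]


def _keys(records, criterion: str) -> set:
    if criterion == "link":
        return {(r, t) for r, t, _, _ in records}
    if criterion == "delay":
        return {(r, t, d) for r, t, d, _ in records}
    if criterion == "effect":
        return {(r, t, s) for r, t, _, s in records}
    raise ValueError(f"unknown criterion {criterion!r}")


def score(inferred, truth, criterion: str, gene_names: Sequence[str] | None = None) -> ConfusionCounts:
    """Confusion counts of deduplicated inferred items against the truth.

    Items are directed pairs (link), (pair, delay) triples (delay) or
    (pair, sign) triples (effect); a true item is a TP iff it appears among
    the inferred items, and every inferred item with no true counterpart is
    an FP.  ``gene_names``, when given, makes unknown names an error.
    """
    inf_rec = _as_records(inferred)
    true_rec = _as_records(truth)
    if gene_names is not None:
        known = set(map(str, gene_names))
        for r, t, _, _ in inf_rec + true_rec:
            if r not in known or t not in known:
                raise ValueError(f"unknown gene name in edge {r} -> {t}")
    inf_keys = _keys(inf_rec, criterion)
    true_keys = _keys(true_rec, criterion)
    tp = len(inf_keys & true_keys)
    return ConfusionCounts(
        tp=tp, fp=len(inf_keys - true_keys), fn=len(true_keys - inf_keys)
    )


def precision_recall_f(counts: ConfusionCounts, criterion: str = "") -> CriterionScores:
    """Precision, recall and F-score; zero denominators yield 0 and set the
    degenerate flag."""
    degenerate = False
    if counts.tp + counts.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        f, degenerate = 0.0, True
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return CriterionScores(criterion, counts, precision, recall, f, degenerate)


def score_all(inferred, truth, gene_names: Sequence[str] | None = None) -> dict[str, CriterionScores]:
    """Link / Delay / Effect scores in one call."""
    return {
        crit: precision_recall_f(score(inferred, truth, crit, gene_names), crit)
        for crit in CRITERIA
    }


def aggregate(scores: Sequence[CriterionScores]) -> dict[str, float]:
    """Arithmetic means of counts and metrics over replicates."""
    if not scores:
        raise ValueError("no scores to aggregate")
    return {
        "tp": float(np.mean([s.counts.tp for s in scores])),
        "fp": float(np.mean([s.counts.fp for s in scores])),
        "fn": float(np.mean([s.counts.fn for s in scores])),
        "precision": float(np.mean([s.precision for s in scores])),
        "recall": float(np.mean([s.recall for s in scores])),
        "f_score": float(np.mean([s.f_score for s in scores])),
    }


@dataclass(frozen=True)
class MethodComparison:
    t_statistic: float
    p_nominal: float
    p_adjusted: float
    degenerate: bool = False


def compare_methods(f_a: Sequence[float], f_b: Sequence[float], n_conditions: int = 1) -> MethodComparison:
    """Welch two-sample t-test of equal mean F-score, with the nominal
    p-value multiplied by the number of tested conditions (capped at 1)."""
    a = np.asarray(f_a, dtype=float)
    b = np.asarray(f_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per sample")
    if np.var(a) == 0 and np.var(b) == 0:
        t = 0.0 if np.mean(a) == np.mean(b) else math.inf
        p = 1.0 if t == 0.0 else 0.0
        return MethodComparison(t, p, min(1.0, p * n_conditions), degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return MethodComparison(float(t), float(p), min(1.0, float(p) * n_conditions))


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def trend_fit(x: Sequence[float], y: Sequence[float]) -> TrendFit:
    """Ordinary least squares of y on x with the standard slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]):
        raise ValueError("all condition values identical; trend undefined")
    if np.all(y == y[0]):  # constant response: zero slope, no explained variance
        return TrendFit(slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0)
    res = stats.linregress(x, y)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
    )
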