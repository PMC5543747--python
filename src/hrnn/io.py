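"""Readers and writers for the package's tab-separated dialects.

Expression matrices: first column the gene name, remaining columns the
time points (header ``gene\tt1...tT``); multiple experiments either as
multiple files or as blank-line-separated blocks in one file.  Edge lists:
``regulator target delay sign weight`` (inferred networks, sign written as
``+``/``-``) or ``regulator target delay effect`` (ground truth).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .evolution import GAConfig
from .inference import ExpressionDataset
from .model import RegulatoryEdge
from .synthetic import SimulationConfig, TrueEdge, TrueNetwork

__all__ = [
    "read_expression",
    "write_expression",
    "read_edges",
    "write_edges",
    "read_truth",
    "write_truth",
    "RunConfig",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


# ---------------------------------------------------------------------------
# expression matrices

def _parse_block(lines: list[tuple[int, str]], path) -> tuple[list[str], np.ndarray]:
    names: list[str] = []
    rows: list[list[float]] = []
    width = None
    for lineno, line in lines:
        cells = line.rstrip("\n").split("\t")
        if lineno == lines[0][0] and cells and cells[0].lower() in ("gene", "name", ""):
            continue  # header row
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ParseError(
                f"{path}:{lineno}: ragged row ({len(cells)} fields, expected {width})"
            )
        names.append(cells[0])
        try:
            rows.append([float(v) for v in cells[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not rows:
        raise ParseError(f"{path}: empty expression block")
    return names, np.array(rows)


def read_expression(paths) -> ExpressionDataset:
    """Read one or more expression files into a dataset.

    Each file may contain several blank-line-separated experiment blocks;
    all blocks must list the same genes in the same order.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    blocks: list[tuple[list[str], np.ndarray]] = []
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"expression file not found: {path}")
        current: list[tuple[int, str]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.strip() == "":
                    if current:
                        blocks.append(_parse_block(current, path))
                        current = []
                    continue
                current.append((lineno, line))
        if current:
            blocks.append(_parse_block(current, path))
    if not blocks:
        raise ParseError("no expression data found")
    names = blocks[0][0]
    if len(set(names)) != len(names):
        raise ParseError(f"duplicate gene names: {names}")
    for other_names, _ in blocks[1:]:
        if other_names != names:
            raise ParseError(
                "experiments disagree on gene names/order: "
                f"{names} vs {other_names}"
            )
    return ExpressionDataset(names, [m for _, m in blocks])


def write_expression(data: ExpressionDataset, path, experiment: int | None = None) -> None:
    """Write a dataset to one file (experiments separated by blank lines)."""
    experiments = (
        data.experiments if experiment is None else [data.experiments[experiment]]
    )
    with open(path, "w") as fh:
        for b, X in enumerate(experiments):
            if b:
                fh.write("\n")
            T = X.shape[1]
            fh.write("gene\t" + "\t".join(f"t{t}" for t in range(1, T + 1)) + "\n")
            for name, row in zip(data.gene_names, X):
                fh.write(name + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# edge lists

_EDGE_HEADER = "regulator\ttarget\tdelay\tsign\tweight"
_TRUTH_HEADER = "regulator\ttarget\tdelay\teffect"


def write_edges(edges: Iterable[RegulatoryEdge], path) -> None:
    with open(path, "w") as fh:
        fh.write(_EDGE_HEADER + "\n")
        for e in edges:
            sign = "+" if e.sign >= 0 else "-"
            fh.write(f"{e.regulator}\t{e.target}\t{e.delay}\t{sign}\t{e.weight!r}\n")


def _parse_delay(cell: str, path, lineno: int) -> int:
    try:
        delay = int(cell)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: malformed delay {cell!r}") from None
    if delay < 1:
        raise ParseError(f"{path}:{lineno}: delay must be >= 1, got {delay}")
    return delay


def read_edges(path) -> list[RegulatoryEdge]:
    """Read an inferred-network edge list (lossless round trip of
    write_edges)."""
    edges: list[RegulatoryEdge] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line == _EDGE_HEADER:
                continue
            cells = line.split("\t")
            if len(cells) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 fields, got {len(cells)}")
            reg, tgt, delay_s, sign_s, weight_s = cells
            if sign_s not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: malformed sign {sign_s!r}")
            delay = _parse_delay(delay_s, path, lineno)
            try:
                weight = float(weight_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed weight {weight_s!r}") from None
            edges.append(
                RegulatoryEdge(reg, tgt, delay, 1 if sign_s == "+" else -1, weight)
            )
    return edges


def write_truth(net: TrueNetwork, path, gene_names: Sequence[str] | None = None) -> None:
    """Write a ground-truth network as a `regulator target delay effect`
    table, using G1..GP names by default."""
    names = list(gene_names) if gene_names else [f"G{i}" for i in range(1, net.P + 1)]
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        for e in net.edges:
            fh.write(
                f"{names[e.regulator - 1]}\t{names[e.target - 1]}\t{e.delay}\t{e.effect!r}\n"
            )


def read_truth(path) -> list[dict]:
    """Read a ground-truth edge table into records usable by the scorer."""
    records: list[dict] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line == _TRUTH_HEADER:
                continue
            cells = line.split("\t")
            if len(cells) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(cells)}")
            reg, tgt, delay_s, effect_s = cells
            delay = _parse_delay(delay_s, path, lineno)
            try:
                effect = float(effect_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed effect {effect_s!r}") from None
            records.append(
                {
                    "regulator": reg,
                    "target": tgt,
                    "delay": delay,
                    "sign": 1 if effect >= 0 else -1,
                    "effect": effect,
                }
            )
    return records


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Nested configuration for a full run; YAML-loadable, every field has a
    documented default, unknown keys are rejected."""

    ga: GAConfig = field(default_factory=GAConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    max_delay: int = 4
    burn_in: int | None = None
    mu_threshold: float = 0.01
    min_weight: float = 0.0
    seed: int | None = None
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "ga" in kwargs and kwargs["ga"] is not None:
            ga_raw = kwargs["ga"]
            bad = set(ga_raw) - set(GAConfig.__dataclass_fields__)
            if bad:
                raise ValueError(f"unknown ga config keys: {sorted(bad)}")
            kwargs["ga"] = GAConfig(**ga_raw)
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            sim_raw = kwargs["simulation"]
            bad = set(sim_raw) - set(SimulationConfig.__dataclass_fields__)
            if bad:
                raise ValueError(f"unknown simulation config keys: {sorted(bad)}")
            kwargs["simulation"] = SimulationConfig(**sim_raw)
        return cls(**kwargs)
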