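"""Node-permutation null models for layer-vs-aggregate centrality correlations.

For each of the nine (centrality measure x situation) cells we observe
the Spearman correlation between the per-individual centrality in one
situation layer and in the aggregate network.  The reference model
permutes node identities *within* each layer independently (preserving
each layer's topology and weights exactly), rebuilds the aggregate from
the permuted layers, recomputes all centralities, and records the
correlation — repeated ``n_iterations`` times (10,000 by default).

The primary p-value is the doubled one-sided count-based permutation
p with the +1 correction,

    p = 2 * min( (1 + #{null >= obs}) / (n + 1),
                 (1 + #{null <= obs}) / (n + 1) ),   capped at 1,

so it is never exactly zero.  The cruder "observed falls outside the
central 95% of the null" criterion is reported alongside as a boolean.
Iterations in which a centrality vector is constant (undefined rank
correlation) are excluded from the null and counted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConsistencyError
from .networks import CENTRALITY_MEASURES, centrality_vectors, to_weight_matrix

SITUATION_ORDER = ("coflight", "nocturnal", "diurnal")


@dataclass
class AnalysisConfig:
    """Settings for the permutation reference model."""

    n_iterations: int = 10_000
    rng_seed: int = 0
    two_sided: bool = True
    pagerank_damping: float = 0.85
    #: retain per-iteration null rho vectors on the report object
    store_null: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConsistencyError("n_iterations must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "AnalysisConfig":
        return cls(**dict(data))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mean ranks for ties).

    Returns ``nan`` when either vector is constant (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    return _pearson(rankdata(x), rankdata(y))


def _pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return float("nan")
    return float((rx @ ry) / denom)


def permute_layer_nodes(layer: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    """Relabel nodes by a uniform random permutation; topology and weights
    are untouched, so all centrality multisets are invariant."""
    nodes = sorted(layer.nodes)
    perm = rng.permutation(len(nodes))
    mapping = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
    return nx.relabel_nodes(layer, mapping, copy=True)


def pvalue(
    observed: float, null: np.ndarray, two_sided: bool = True
) -> tuple[float, bool]:
    """Count-based permutation p-value and the outside-central-95% flag."""
    null = np.asarray(null, dtype=float)
    null = null[~np.isnan(null)]
    if null.size == 0:
        raise ConsistencyError("empty null distribution")
    if np.isnan(observed):
        return float("nan"), False
    n = null.size
    p_hi = (1 + np.sum(null >= observed)) / (n + 1)
    p_lo = (1 + np.sum(null <= observed)) / (n + 1)
    p = 2 * min(p_hi, p_lo) if two_sided else min(p_hi, p_lo)
    q_lo, q_hi = np.quantile(null, [0.025, 0.975])
    outside = bool(observed < q_lo or observed > q_hi)
    return float(min(p, 1.0)), outside


def spearman_permutation_null(
    x: Sequence[float], y: Sequence[float], n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    """Null Spearman rho from ``n_iter`` random permutations of ``x`` against ``y``.

    Vectorized helper used for calibration studies of the count-based
    p-value machinery.
    """
    rx = rankdata(np.asarray(x, dtype=float))
    ry = rankdata(np.asarray(y, dtype=float))
    n = rx.size
    perms = rng.permuted(np.tile(rx, (n_iter, 1)), axis=1)
    pc = perms - perms.mean(axis=1, keepdims=True)
    yc = ry - ry.mean()
    denom = np.sqrt((pc * pc).sum(axis=1) * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (pc @ yc) / denom


@dataclass
class CellResult:
    """Observed statistic and null summary for one (measure, situation) cell."""

    measure: str
    situation: str
    observed_rho: float
    p_value: float
    outside_central_95: bool
    null_q025: float
    null_q975: float
    n_valid: int
    n_excluded: int
    null: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "measure": self.measure,
            "situation": self.situation,
            "observed_rho": _json_float(self.observed_rho),
            "p_value": _json_float(self.p_value),
            "outside_central_95": self.outside_central_95,
            "null_q025": _json_float(self.null_q025),
            "null_q975": _json_float(self.null_q975),
            "n_valid": self.n_valid,
            "n_excluded": self.n_excluded,
        }
        return d


def _json_float(x: float):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)


@dataclass
class PermutationReport:
    """Nine-cell report of observed rho, permutation p, and null quantiles."""

    cells: dict[tuple[str, str], CellResult]
    n_iterations: int
    rng_seed: int
    two_sided: bool = True

    def cell(self, measure: str, situation: str) -> CellResult:
        return self.cells[(measure, situation)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_dict() for c in self.cells.values()])

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "rng_seed": self.rng_seed,
            "two_sided": self.two_sided,
            "cells": {
                f"{m}_{s}": c.to_dict() for (m, s), c in sorted(self.cells.items())
            },
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def null_frame(self) -> pd.DataFrame:
        """Per-iteration null rho values in long format (for audit dumps)."""
        frames = []
        for (m, s), c in sorted(self.cells.items()):
            if c.null is None:
                continue
            frames.append(
                pd.DataFrame({"measure": m, "situation": s, "rho": c.null})
            )
        if not frames:
            return pd.DataFrame(columns=["measure", "situation", "rho"])
        return pd.concat(frames, ignore_index=True)


def run_reference_model(
    layers: Mapping[str, nx.Graph], cfg: AnalysisConfig
) -> PermutationReport:
    """Observed layer-vs-aggregate Spearman correlations with their
    within-layer node-permutation null distributions.

    ``layers`` maps situation labels to graphs sharing one node set.
    All randomness flows from ``cfg.rng_seed``; per-iteration generators
    are spawned deterministically, so the report is bitwise reproducible.
    """
    situations = [s for s in SITUATION_ORDER if s in layers]
    situations += [s for s in layers if s not in situations]
    nodes = sorted(layers[situations[0]].nodes)
    for s in situations:
        if sorted(layers[s].nodes) != nodes:
            raise ConsistencyError("layers must share one node set")
    n = len(nodes)
    weights = {s: to_weight_matrix(layers[s], nodes) for s in situations}
    damping = cfg.pagerank_damping

    # observed statistics
    layer_cent = {s: centrality_vectors(weights[s], damping) for s in situations}
    agg_cent = centrality_vectors(sum(weights.values()), damping)
    observed = {
        (m, s): spearman_rho(layer_cent[s][m], agg_cent[m])
        for m in CENTRALITY_MEASURES
        for s in situations
    }

    # layer ranks are permutation-covariant: precompute once
    layer_ranks = {
        (m, s): rankdata(layer_cent[s][m]) for m in CENTRALITY_MEASURES for s in situations
    }

    nulls = {key: np.full(cfg.n_iterations, np.nan) for key in observed}
    children = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.n_iterations)
    for it in range(cfg.n_iterations):
        rng = np.random.default_rng(children[it])
        perms = {s: rng.permutation(n) for s in situations}
        agg_w = np.zeros((n, n))
        for s in situations:
            p = perms[s]
            agg_w += weights[s][np.ix_(p, p)]
        agg_it = centrality_vectors(agg_w, damping)
        agg_ranks = {m: rankdata(agg_it[m]) for m in CENTRALITY_MEASURES}
        for m in CENTRALITY_MEASURES:
            for s in situations:
                nulls[(m, s)][it] = _pearson(layer_ranks[(m, s)][perms[s]], agg_ranks[m])

    cells: dict[tuple[str, str], CellResult] = {}
    for key, obs in observed.items():
        null = nulls[key]
        valid = null[~np.isnan(null)]
        n_excluded = int(null.size - valid.size)
        if valid.size == 0 or np.isnan(obs):
            cells[key] = CellResult(
                measure=key[0],
                situation=key[1],
                observed_rho=obs,
                p_value=float("nan"),
                outside_central_95=False,
                null_q025=float("nan"),
                null_q975=float("nan"),
                n_valid=int(valid.size),
                n_excluded=n_excluded,
                null=valid if cfg.store_null else None,
            )
            continue
        p, outside = pvalue(obs, valid, two_sided=cfg.two_sided)
        q_lo, q_hi = np.quantile(valid, [0.025, 0.975])
        cells[key] = CellResult(
            measure=key[0],
            situation=key[1],
            observed_rho=obs,
            p_value=p,
            outside_central_95=outside,
            null_q025=float(q_lo),
            null_q975=float(q_hi),
            n_valid=int(valid.size),
            n_excluded=n_excluded,
            null=valid if cfg.store_null else None,
        )
    return PermutationReport(
        cells=cells,
        n_iterations=cfg.n_iterations,
        rng_seed=cfg.rng_seed,
        two_sided=cfg.two_sided,
    )
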