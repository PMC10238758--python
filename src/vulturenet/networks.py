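"""SRI-weighted situation networks, their aggregate, and node centralities.

Each situation yields an undirected weighted graph on the full filtered
cohort (isolates included).  Edge weight is the simple ratio index

    SRI = (sampling units observed together) / (units both were observed),

which lies in (0, 1] for emitted edges; a pair never simultaneously
sampled gets no edge rather than weight zero.  The aggregate network
sums the three layer weights per pair.  Centralities are degree (unique
partners), strength (sum of incident weights) and weighted PageRank
(damped random walk with edge-weight-proportional transitions; dangling
mass redistributed uniformly).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConsistencyError

CENTRALITY_MEASURES = ("degree", "strength", "pagerank")


def compute_sri(together: float, joint_sampled: float) -> float:
    """Simple ratio index; caller must omit the pair when joint_sampled == 0."""
    if together < 0 or joint_sampled < 0:
        raise ConsistencyError("counts must be non-negative")
    if together > joint_sampled:
        raise ConsistencyError(
            f"together ({together}) exceeds joint sampling ({joint_sampled})"
        )
    if joint_sampled == 0:
        raise ConsistencyError("SRI undefined for joint_sampled == 0; omit the pair")
    return together / joint_sampled


def build_layer(
    together: pd.DataFrame,
    denominators: pd.DataFrame,
    cohort: Sequence[str],
    situation: str,
) -> nx.Graph:
    """Build one situation network from numerator/denominator matrices.

    Nodes are the full cohort; an edge is emitted for pairs with
    ``together > 0`` and ``joint_sampled > 0`` and carries attributes
    ``together``, ``joint_sampled`` and ``weight`` (the SRI).
    """
    ids = sorted(cohort)
    extra = set(together.index) - set(ids)
    if extra:
        raise ConsistencyError(f"event individuals outside cohort: {sorted(extra)}")
    g = nx.Graph(situation=str(situation))
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            tog = int(together.at[a, b]) if a in together.index and b in together.columns else 0
            joint = int(denominators.at[a, b]) if a in denominators.index and b in denominators.columns else 0
            if tog > 0 and joint > 0:
                g.add_edge(a, b, together=tog, joint_sampled=joint, weight=compute_sri(tog, joint))
            elif tog > joint:
                raise ConsistencyError(f"pair ({a}, {b}): together {tog} > joint {joint}")
    return g


def build_aggregate(layers: Mapping[str, nx.Graph]) -> nx.Graph:
    """Sum edge weights across layers; node sets must be identical."""
    graphs = list(layers.values())
    nodes = set(graphs[0].nodes)
    for g in graphs[1:]:
        if set(g.nodes) != nodes:
            raise ConsistencyError("layer node sets differ; cannot aggregate")
    agg = nx.Graph(situation="aggregate")
    agg.add_nodes_from(sorted(nodes))
    for g in graphs:
        for a, b, w in g.edges(data="weight"):
            if agg.has_edge(a, b):
                agg[a][b]["weight"] += w
            else:
                agg.add_edge(a, b, weight=w)
    return agg


def to_weight_matrix(g: nx.Graph, nodelist: Sequence[str] | None = None) -> np.ndarray:
    nodelist = list(nodelist) if nodelist is not None else sorted(g.nodes)
    return nx.to_numpy_array(g, nodelist=nodelist, weight="weight")


def pagerank_matrix(
    weights: np.ndarray,
    damping: float = 0.85,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Weighted PageRank by power iteration on a dense symmetric matrix.

    Transition probabilities are proportional to edge weights; rows with
    zero strength (isolates) teleport uniformly, so the scores always
    form a proper distribution.  Convergence is declared when the L1
    change drops below ``tol``.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if n == 0:
        return np.zeros(0)
    strength = w.sum(axis=1)
    dangling = strength == 0
    p = np.zeros_like(w)
    nz = ~dangling
    p[nz] = w[nz] / strength[nz, None]
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = damping * (x @ p) + (damping * x[dangling].sum() + 1.0 - damping) / n
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    # snap away sub-tolerance iteration noise so exactly-symmetric nodes
    # receive exactly equal scores (their ranks would otherwise be noise)
    return np.round(x, 12)


def centrality_vectors(
    weights: np.ndarray, damping: float = 0.85
) -> dict[str, np.ndarray]:
    """degree / strength / pagerank from a dense weight matrix."""
    w = np.asarray(weights, dtype=float)
    return {
        "degree": (w > 0).sum(axis=1).astype(float),
        "strength": w.sum(axis=1),
        "pagerank": pagerank_matrix(w, damping=damping),
    }


def centralities(g: nx.Graph, damping: float = 0.85) -> pd.DataFrame:
    """Per-node centrality table (degree, strength, pagerank)."""
    nodes = sorted(g.nodes)
    vecs = centrality_vectors(to_weight_matrix(g, nodes), damping=damping)
    out = pd.DataFrame(vecs, index=pd.Index(nodes, name="individual_id"))
    out["degree"] = out["degree"].astype(int)
    return out


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "id_a": a,
            "id_b": b,
            "situation": g.graph.get("situation", ""),
            "together": d.get("together", np.nan),
            "joint_sampled": d.get("joint_sampled", np.nan),
            "sri": d["weight"],
        }
        for a, b, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["id_a", "id_b", "situation", "together", "joint_sampled", "sri"])


def write_edgelist_csv(g: nx.Graph, path) -> None:
    edge_table(g).to_csv(path, index=False)


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def centrality_table(networks: Mapping[str, nx.Graph], damping: float = 0.85) -> pd.DataFrame:
    """Long-format centralities for several networks (layers + aggregate)."""
    frames = []
    for name, g in networks.items():
        c = centralities(g, damping=damping).reset_index()
        c.insert(1, "network", name)
        frames.append(c)
    return pd.concat(frames, ignore_index=True)
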