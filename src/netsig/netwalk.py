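"""Random-walk network expansion of a gene signature.

Biomarker genes seed a random walk with restart (RWR) over a background
protein-interaction network, with restart mass proportional to
-log2(filter p-value).  Edges are scored by the log2 ratio of the
score-weighted stationary flux to the flux of a uniform-restart
baseline walk, a step in the sorted edge scores picks a retention
threshold, and the above-threshold edges induce the expanded
subnetwork.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "NodeScores",
    "Subnetwork",
    "assign_node_scores",
    "random_walk",
    "edge_scores",
    "detect_threshold",
    "extract_subnetwork",
]

#: L1 convergence tolerance for the RWR fixed-point iteration.
RWR_TOL = 1e-10
#: Iteration cap before the walk is declared non-convergent.
RWR_MAX_ITER = 10_000


@dataclass
class NodeScores:
    """Gene -> nonnegative restart score; seeds carry -log2 p."""

    scores: dict[str, float]
    missing_genes: list[str] = field(default_factory=list)
    epsilon: float = 0.0

    def as_vector(self, nodes: list[str]) -> np.ndarray:
        return np.array([self.scores[n] for n in nodes])


@dataclass
class Subnetwork:
    """Edges retained above the score threshold and the induced genes."""

    edges: list[tuple[str, str, float]]
    genes: list[str]
    components: list[list[str]]
    threshold: float

    @property
    def largest_component(self) -> list[str]:
        return max(self.components, key=len) if self.components else []


def _check_simple(network: nx.Graph) -> nx.Graph:
    if network.is_directed() or network.is_multigraph():
        raise ValueError("network must be a simple undirected graph")
    if any(u == v for u, v in network.edges):
        raise ValueError("network must not contain self-loops")
    return network


def assign_node_scores(
    network: nx.Graph,
    biomarker_pvalues: dict[str, float],
    epsilon: float | None = None,
) -> NodeScores:
    """Map biomarker filter p-values to node scores on the network.

    Biomarker genes present in the network get -log2(p); every other
    node gets a small baseline ``epsilon`` (default: 1e-3 of the
    smallest positive biomarker score) that keeps the restart vector
    strictly positive and the walk irreducible.  Zero scores (p = 1)
    are floored at epsilon too.  Biomarker genes absent from the
    network are reported, not silently dropped.
    """
    _check_simple(network)
    in_net = {g: p for g, p in biomarker_pvalues.items() if g in network}
    missing = sorted(set(biomarker_pvalues) - set(in_net))
    if missing:
        logger.warning(
            "%d biomarker genes absent from the network: %s",
            len(missing), ", ".join(missing[:10]),
        )
    raw = {g: -np.log2(max(p, np.finfo(float).tiny)) for g, p in in_net.items()}
    positive = [s for s in raw.values() if s > 0]
    if epsilon is None:
        epsilon = 1e-3 * min(positive) if positive else 1e-6
    scores = {n: float(epsilon) for n in network.nodes}
    for g, s in raw.items():
        scores[g] = float(max(s, epsilon))
    return NodeScores(scores=scores, missing_genes=missing, epsilon=float(epsilon))


def _column_stochastic(network: nx.Graph, nodes: list[str]) -> sparse.csr_matrix:
    """Column-normalized adjacency: W[i, j] = P(step to i | at j)."""
    adj = nx.to_scipy_sparse_array(network, nodelist=nodes, format="csc", dtype=float)
    deg = np.asarray(adj.sum(axis=0)).ravel()
    if np.any(deg == 0):
        raise ValueError("isolated nodes make the walk ill-defined")
    return sparse.csr_matrix(adj @ sparse.diags(1.0 / deg))


def random_walk(
    network: nx.Graph,
    scores: NodeScores,
    restart_prob: float = 0.5,
) -> pd.Series:
    """Stationary distribution of the RWR: pi = (1-r) W pi + r s.

    ``s`` is the score vector normalized to sum 1; the fixed point is
    found by power iteration to an L1 tolerance of 1e-10.  Returns a
    Series over nodes summing to 1.
    """
    _check_simple(network)
    if not (0 < restart_prob < 1):
        raise ValueError("restart_prob must be in (0, 1)")
    nodes = list(network.nodes)
    s = scores.as_vector(nodes)
    if s.sum() <= 0:
        raise ValueError("restart vector must have positive mass")
    s = s / s.sum()
    W = _column_stochastic(network, nodes)
    pi = s.copy()
    for it in range(RWR_MAX_ITER):
        nxt = (1.0 - restart_prob) * (W @ pi) + restart_prob * s
        delta = float(np.abs(nxt - pi).sum())
        pi = nxt
        if delta < RWR_TOL:
            break
    else:
        raise RuntimeError(
            f"RWR did not converge in {RWR_MAX_ITER} iterations "
            f"(last L1 change {delta:.3e}, r={restart_prob})"
        )
    pi = pi / pi.sum()
    assert np.all(pi >= 0) and abs(pi.sum() - 1) < 1e-9
    return pd.Series(pi, index=nodes)


def edge_scores(
    network: nx.Graph,
    scores: NodeScores,
    restart_prob: float = 0.5,
    mode: str = "min_ratio",
) -> pd.DataFrame:
    """Score every edge by its stationary random-walk flux.

    The directed flux along u->v is pi(u) * W(v|u) = pi(u)/deg(u).
    Three scorings are available:

    ``min_ratio`` (default)
        log2 of the smaller directed flux under the score-weighted walk
        over the smaller directed flux under a uniform-restart baseline
        walk.  High only when *both* endpoints carry elevated
        stationary mass, so module-internal edges separate sharply from
        edges that merely touch one seeded gene.
    ``sum_ratio``
        log2 of the symmetrized (summed) flux ratio; smoother, retains
        every edge incident to a seeded gene.
    ``raw``
        the summed weighted flux itself, no baseline.

    A uniformly seeded walk scores every edge 0 under either ratio
    mode.  Result is sorted by score descending, ties by edge name.
    """
    _check_simple(network)
    if mode not in ("min_ratio", "sum_ratio", "raw"):
        raise ValueError("mode must be 'min_ratio', 'sum_ratio' or 'raw'")
    nodes = list(network.nodes)
    deg = np.array([network.degree[n] for n in nodes], dtype=float)
    node_ix = {n: i for i, n in enumerate(nodes)}

    per_node_w = random_walk(network, scores, restart_prob).to_numpy() / deg
    rows = []
    if mode == "raw":
        for u, v in network.edges:
            rows.append((u, v, float(per_node_w[node_ix[u]] + per_node_w[node_ix[v]])))
    else:
        uniform = NodeScores(scores={n: 1.0 for n in nodes})
        per_node_b = random_walk(network, uniform, restart_prob).to_numpy() / deg
        combine = min if mode == "min_ratio" else lambda a, b: a + b
        for u, v in network.edges:
            fw = combine(per_node_w[node_ix[u]], per_node_w[node_ix[v]])
            fb = combine(per_node_b[node_ix[u]], per_node_b[node_ix[v]])
            score = np.log2(fw / fb) if fb > 0 else -np.inf
            rows.append((u, v, float(score)))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])
    return df.sort_values(
        ["score", "gene_a", "gene_b"], ascending=[False, True, True]
    ).reset_index(drop=True)


def detect_threshold(
    scores: np.ndarray | list[float],
    gap_factor: float = 3.0,
    fallback_top_k: int = 10,
    min_block: int = 10,
) -> tuple[float, bool]:
    """Locate the step in the sorted edge-score curve.

    Sorts scores descending and finds the largest gap between
    consecutive values whose upper value lies at or above the median —
    restricting to the upper half keeps the cut well above the bulk of
    near-baseline scores.  A gap qualifies only if at least
    ``min_block`` edges sit above it (a step separates two substantial
    blocks; without this, a single outlying top edge wins).  The step
    counts as "obvious" when the winning gap exceeds ``gap_factor``
    times the median candidate gap; otherwise the scores decay smoothly
    and the function falls back to keeping the top ``fallback_top_k``
    edges, with a warning.  Returns ``(threshold, obvious_step)``; the
    threshold is the gap midpoint.
    """
    arr = np.sort(np.asarray(scores, dtype=float))[::-1]
    arr = arr[np.isfinite(arr)]
    if len(np.unique(arr)) < 3:
        raise ValueError("need at least 3 distinct scores to detect a step")
    med = float(np.median(arr))
    gaps = arr[:-1] - arr[1:]
    candidate = arr[:-1] >= med
    if len(arr) > min_block + 2:
        candidate &= np.arange(len(gaps)) >= min_block
    if not candidate.any():
        k = min(fallback_top_k, len(arr) - 1)
        logger.warning("no candidate gaps; keeping top %d edges", k)
        return float((arr[k - 1] + arr[k]) / 2.0), False
    cand_gaps = gaps[candidate]
    ref = float(np.median(cand_gaps[cand_gaps > 0])) if np.any(cand_gaps > 0) else 0.0
    i_best = int(np.argmax(np.where(candidate, gaps, -np.inf)))
    best_gap = gaps[i_best]
    obvious = ref > 0 and best_gap > gap_factor * ref
    if not obvious:
        k = min(fallback_top_k, len(arr) - 1)
        logger.warning(
            "no obvious step in sorted edge scores; keeping top %d edges", k
        )
        return float((arr[k - 1] + arr[k]) / 2.0), False
    return float((arr[i_best] + arr[i_best + 1]) / 2.0), True


def extract_subnetwork(
    network: nx.Graph,
    edge_table: pd.DataFrame,
    threshold: float,
    largest_only: bool = False,
) -> Subnetwork:
    """Edges with score strictly above the threshold and induced genes.

    All connected components are kept by default, with sizes logged and
    the largest flagged; ``largest_only=True`` restricts the gene list
    to the largest component.
    """
    _check_simple(network)
    kept = edge_table[edge_table["score"] > threshold]
    g = nx.Graph()
    edges = [
        (str(r.gene_a), str(r.gene_b), float(r.score))
        for r in kept.itertuples(index=False)
    ]
    g.add_weighted_edges_from(edges)
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=len, reverse=True)
    if len(components) > 1:
        logger.info(
            "subnetwork split into %d components of sizes %s",
            len(components), [len(c) for c in components],
        )
    if largest_only and components:
        genes = components[0]
        keep = set(genes)
        edges = [(u, v, w) for u, v, w in edges if u in keep and v in keep]
    else:
        genes = sorted(g.nodes)
    return Subnetwork(
        edges=edges, genes=genes, components=components, threshold=float(threshold)
    )
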